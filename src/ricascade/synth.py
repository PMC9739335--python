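"""Synthetic study-system generators.

Emulates the four inputs the barrier pipeline consumes — species occurrences
on an environmental grid, flowering-onset records, pollination-cross outcome
counts, and a phylogeny — with known ground truth, so that downstream
estimates (niche overlap, barrier strengths) can be checked against the
quantities they are supposed to recover.

Every generator is deterministic given the scenario config's ``rng_seed``;
independent operations draw from seed streams derived from the root seed and
a stable operation tag.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .config import GRADIENT_LAYER, ConfigurationError, ScenarioConfig
from .grid import EnvGrid, OccurrenceSet, SuitabilitySurface


class SimulationError(RuntimeError):
    """Raised when a scenario cannot produce the requested sample."""


@dataclass
class FloweringRecord:
    """First-flowering observation for one plant within one season."""

    record_id: str
    species: str
    onset_day: int
    source: str  # garden | wild
    year: int
    block: str | None = None


@dataclass
class CrossRecord:
    """Pooled outcome counts of hand pollinations for one acceptor/donor pair."""

    acceptor: str
    donor: str
    treatment: str  # within | between
    n_pollinations: int
    n_fruits: int
    n_seeds_total: int
    n_seeds_viable: int
    n_pollen_total: int | None = None
    n_pollen_germinated: int | None = None

    def __post_init__(self) -> None:
        if self.treatment not in ("within", "between"):
            raise ValueError(f"treatment must be within|between, got {self.treatment!r}")
        if (self.treatment == "within") != (self.acceptor == self.donor):
            raise ValueError(
                f"treatment {self.treatment!r} inconsistent with pair "
                f"{self.acceptor!r} x {self.donor!r}"
            )
        if not 0 <= self.n_fruits <= self.n_pollinations:
            raise ValueError("need 0 <= n_fruits <= n_pollinations")
        if not 0 <= self.n_seeds_viable <= self.n_seeds_total:
            raise ValueError("need 0 <= n_seeds_viable <= n_seeds_total")
        if (self.n_pollen_total is None) != (self.n_pollen_germinated is None):
            raise ValueError("pollen counts must both be present or both absent")
        if self.n_pollen_total is not None:
            if not 0 <= self.n_pollen_germinated <= self.n_pollen_total:
                raise ValueError("need 0 <= n_pollen_germinated <= n_pollen_total")


def _stream(root_seed: int, *tags: str) -> np.random.Generator:
    """Derive an independent RNG stream from the root seed and string tags."""
    keys = [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng([int(root_seed) & 0x7FFFFFFF, *keys])


def _smooth_field(rng: np.random.Generator, lons: np.ndarray, lats: np.ndarray,
                  amplitude: float, n_waves: int = 4) -> np.ndarray:
    """Smooth random field: a sum of random-phase, random-direction sinusoids."""
    if amplitude == 0:
        return np.zeros_like(lons)
    field = np.zeros_like(lons)
    span = max(lons.max() - lons.min(), lats.max() - lats.min())
    for _ in range(n_waves):
        freq = rng.uniform(0.5, 2.0) / span
        theta = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        field += np.sin(2 * np.pi * freq * (np.cos(theta) * lons + np.sin(theta) * lats) + phase)
    return amplitude * field / n_waves


def make_environment(config: ScenarioConfig) -> EnvGrid:
    """Build the synthetic environmental raster.

    Layers:

    ``temp_north``
        Linear north–south gradient, 0 at the southern edge to 100 at the
        northern edge, plus smooth low-frequency noise.  This is the axis the
        default species niches are spaced along, emulating a regional
        aridity/temperature gradient.
    ``precip_east``
        Linear west–east gradient (0–100) plus noise.
    ``seasonality``
        A smooth non-monotone climate summary, largest toward both extremes of
        the thermal gradient: ``(temp_north - 50)^2 / 25``.  Because it is an
        exact quadratic in ``temp_north``, a linear-terms-only logistic model
        over the layer set can express quadratic (i.e. Gaussian-bell)
        log-odds along the gradient.
    ``elevation``
        Pure smooth noise field, uninformative about the niches.
    """
    lon_min, lon_max, lat_min, lat_max = config.grid_extent
    res = config.grid_resolution
    # small tolerance so extents that are exact multiples of res survive float division
    n_cols = int(np.floor((lon_max - lon_min) / res + 1e-9))
    n_rows = int(np.floor((lat_max - lat_min) / res + 1e-9))
    if n_cols < 1 or n_rows < 1:
        raise ConfigurationError(
            f"extent {config.grid_extent} too small for resolution {res}"
        )
    mask = np.ones((n_rows, n_cols), dtype=bool)
    grid = EnvGrid(config.grid_extent, res, {}, mask)
    lons, lats = grid.cell_centers()

    rng = _stream(config.rng_seed, "environment")
    amp = config.env_noise_amplitude
    temp = 100.0 * (lats - lat_min) / (grid.lat_top - lat_min)
    temp = temp + _smooth_field(rng, lons, lats, amp)
    precip = 100.0 * (lons - lon_min) / (lon_max - lon_min)
    precip = precip + _smooth_field(rng, lons, lats, amp)
    seasonality = (temp - 50.0) ** 2 / 25.0
    elevation = 500.0 + _smooth_field(rng, lons, lats, max(amp, 1.0) * 100.0)

    grid.layers = {
        GRADIENT_LAYER: temp,
        "precip_east": precip,
        "seasonality": seasonality,
        "elevation": elevation,
    }
    return grid


def true_suitability(config: ScenarioConfig, env: EnvGrid, species: str) -> SuitabilitySurface:
    """Ground-truth suitability: product of per-layer Gaussian niche kernels.

    For each layer the species has an optimum for, the kernel is
    ``exp(-(x - optimum)^2 / (2 breadth^2))``; layers without an optimum are
    unconstrained.  The product is rescaled so its maximum over valid cells
    is 1.
    """
    config.require_species(species)
    optima = config.niche_optima.get(species, {})
    breadths = config.niche_breadths.get(species, {})
    values = np.ones(env.shape, dtype=float)
    for layer, opt in optima.items():
        if layer not in env.layers:
            raise KeyError(f"niche layer {layer!r} not in environment {list(env.layers)}")
        if layer not in breadths:
            raise ConfigurationError(f"no niche breadth for {species!r} on layer {layer!r}")
        sd = breadths[layer]
        values *= np.exp(-((env.layers[layer] - opt) ** 2) / (2.0 * sd**2))
    peak = values[env.mask].max() if env.mask.any() else 0.0
    if peak > 0:
        values = values / peak
    values = np.where(env.mask, values, np.nan)
    return SuitabilitySurface(species=species, values=values, grid=env, normalized=False)


def simulate_occurrences(config: ScenarioConfig, env: EnvGrid, species: str) -> OccurrenceSet:
    """Draw presence points: cells sampled without replacement proportionally
    to true suitability, one point per drawn cell jittered within the cell."""
    config.require_species(species)
    n = config.n_presences.get(species)
    if n is None:
        raise ConfigurationError(f"no n_presences configured for {species!r}")
    surf = true_suitability(config, env, species)
    weights = np.where(env.mask, np.nan_to_num(surf.values), 0.0).ravel()
    positive = int((weights > 0).sum())
    if n > positive:
        raise SimulationError(
            f"{species!r}: requested {n} presences but only {positive} cells "
            "have positive suitability"
        )
    rng = _stream(config.rng_seed, "occurrences", species)
    idx = rng.choice(weights.size, size=n, replace=False, p=weights / weights.sum())
    rows, cols = np.unravel_index(idx, env.shape)
    lons, lats = env.cell_centers()
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * env.resolution
    pts = np.column_stack([lons[rows, cols] + jitter[:, 0], lats[rows, cols] + jitter[:, 1]])
    return OccurrenceSet(species=species, points=pts, role="presence")


def simulate_flowering(
    config: ScenarioConfig,
    species: str,
    n_records: int,
    source: str = "garden",
    year: int = 0,
    year_effect: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[FloweringRecord]:
    """Draw flowering-onset records.

    Onset days are Normal(mean + year_effect, sd), rounded and truncated to
    [1, season_length]; block labels are assigned round-robin over
    ``config.n_blocks`` spatial blocks.
    """
    config.require_species(species)
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if source not in ("garden", "wild"):
        raise ValueError(f"source must be garden|wild, got {source!r}")
    mean = config.flowering_mean.get(species)
    sd = config.flowering_sd.get(species)
    if mean is None or sd is None:
        raise ConfigurationError(f"no flowering parameters for {species!r}")
    if sd <= 0:
        raise ConfigurationError(f"flowering_sd for {species!r} must be > 0")
    if rng is None:
        rng = _stream(config.rng_seed, "flowering", species, source, str(year))
    days = np.rint(rng.normal(mean + year_effect, sd, size=n_records))
    days = np.clip(days, 1, config.season_length).astype(int)
    return [
        FloweringRecord(
            record_id=f"{species}-{source}-{year}-{i}",
            species=species,
            onset_day=int(d),
            source=source,
            year=year,
            block=f"block_{i % config.n_blocks + 1}" if source == "garden" else None,
        )
        for i, d in enumerate(days)
    ]


def simulate_crosses(
    config: ScenarioConfig,
    acceptor: str,
    donor: str,
    n_pollinations: int,
    pollen_grains_per_stigma: int = 50,
    rng: np.random.Generator | None = None,
) -> CrossRecord:
    """Draw one pooled cross-experiment record for a directed pair.

    Fruits are Binomial(n_pollinations, fruit_prob); each fruit carries
    Poisson(seeds_per_fruit_mean) seeds of which Binomial(seeds, seed_viab)
    are viable; pollen germination is Binomial over the deposited grains.
    Within/between parameters are selected by whether acceptor == donor.
    """
    config.require_species(acceptor)
    config.require_species(donor)
    within = acceptor == donor
    suffix = "within" if within else "between"
    try:
        fruit_p = getattr(config, f"fruit_prob_{suffix}")[acceptor]
        viab_p = getattr(config, f"seed_viab_{suffix}")[acceptor]
        germ_p = getattr(config, f"pollen_germ_{suffix}")[acceptor]
    except KeyError as exc:
        raise KeyError(f"no {suffix}-cross parameters for acceptor {acceptor!r}") from exc
    if rng is None:
        rng = _stream(config.rng_seed, "crosses", acceptor, donor)
    n_fruits = int(rng.binomial(n_pollinations, fruit_p))
    n_seeds = int(rng.poisson(config.seeds_per_fruit_mean * n_fruits)) if n_fruits else 0
    n_viable = int(rng.binomial(n_seeds, viab_p)) if n_seeds else 0
    n_pollen = pollen_grains_per_stigma * n_pollinations
    n_germ = int(rng.binomial(n_pollen, germ_p)) if n_pollen else 0
    return CrossRecord(
        acceptor=acceptor,
        donor=donor,
        treatment=suffix,
        n_pollinations=n_pollinations,
        n_fruits=n_fruits,
        n_seeds_total=n_seeds,
        n_seeds_viable=n_viable,
        n_pollen_total=n_pollen,
        n_pollen_germinated=n_germ,
    )


def simulate_tree(species: list[str] | int, rng_seed: int = 0) -> str:
    """Random bifurcating ultrametric-style tree over the species, as Newick.

    Built by successive random pairwise joins with exponentially distributed
    waiting times, so all branch lengths are positive.
    """
    if isinstance(species, int):
        if species < 2:
            raise ConfigurationError("need at least 2 species for a tree")
        labels = [f"species_{i + 1}" for i in range(species)]
    else:
        labels = list(species)
        if len(labels) < 2:
            raise ConfigurationError("need at least 2 species for a tree")
    rng = _stream(rng_seed, "tree")
    # (newick fragment without length, height) per live lineage
    nodes: list[tuple[str, float]] = [(lab, 0.0) for lab in labels]
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.exponential(1.0 / len(nodes)))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = f"({na}:{height - ha:.6f},{nb}:{height - hb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append((merged, height))
    return nodes[0][0] + ";"
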