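"""Scenario and pipeline configuration objects.

A :class:`ScenarioConfig` fully specifies a synthetic study system: the
environmental grid, each species' Gaussian niche, its flowering-onset
distribution, and the success probabilities of within- versus between-species
crosses.  All generators in :mod:`ricascade.synth` are pure functions of a
config plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a scenario or pipeline configuration is invalid."""


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic multi-species study system.

    Parameters
    ----------
    species
        Ordered species labels.
    grid_extent
        (lon_min, lon_max, lat_min, lat_max) in decimal degrees.
    grid_resolution
        Cell size in degrees.
    niche_optima, niche_breadths
        Per species, a mapping from environment-layer name to the Gaussian
        niche optimum / standard deviation in that layer's units.  Layers a
        species does not mention are unconstrained.
    n_presences
        Per-species number of simulated presence points.
    flowering_mean, flowering_sd
        Per-species mean and s.d. of flowering-onset day within the season.
    season_length
        Length of the flowering season in days (day 1 = season start).
    fruit_prob_within / fruit_prob_between, seed_viab_*, pollen_germ_*
        Per-acceptor success probabilities for conspecific vs heterospecific
        crosses.
    seeds_per_fruit_mean
        Poisson mean of seeds per fruit.
    rng_seed
        Root seed; every generator derives its stream from this.
    """

    species: list[str]
    grid_extent: tuple[float, float, float, float] = (34.0, 36.0, 29.4, 33.3)
    grid_resolution: float = 0.05
    niche_optima: dict[str, dict[str, float]] = field(default_factory=dict)
    niche_breadths: dict[str, dict[str, float]] = field(default_factory=dict)
    n_presences: dict[str, int] = field(default_factory=dict)
    flowering_mean: dict[str, float] = field(default_factory=dict)
    flowering_sd: dict[str, float] = field(default_factory=dict)
    season_length: int = 150
    n_blocks: int = 4
    fruit_prob_within: dict[str, float] = field(default_factory=dict)
    fruit_prob_between: dict[str, float] = field(default_factory=dict)
    seed_viab_within: dict[str, float] = field(default_factory=dict)
    seed_viab_between: dict[str, float] = field(default_factory=dict)
    pollen_germ_within: dict[str, float] = field(default_factory=dict)
    pollen_germ_between: dict[str, float] = field(default_factory=dict)
    seeds_per_fruit_mean: float = 20.0
    env_noise_amplitude: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.grid_extent
        if self.grid_resolution <= 0:
            raise ConfigurationError("grid_resolution must be positive")
        if lon_max <= lon_min or lat_max <= lat_min:
            raise ConfigurationError(f"empty grid extent {self.grid_extent}")
        if len(set(self.species)) != len(self.species):
            raise ConfigurationError("duplicate species labels")
        for sp, n in self.n_presences.items():
            if n < 1:
                raise ConfigurationError(f"n_presences[{sp!r}] must be >= 1")
        for sp, breadths in self.niche_breadths.items():
            for layer, b in breadths.items():
                if b <= 0:
                    raise ConfigurationError(
                        f"niche breadth for {sp!r} on layer {layer!r} must be > 0"
                    )
        for name in (
            "fruit_prob_within", "fruit_prob_between",
            "seed_viab_within", "seed_viab_between",
            "pollen_germ_within", "pollen_germ_between",
        ):
            for sp, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{name}[{sp!r}]={p} outside [0, 1]")
        if self.seeds_per_fruit_mean <= 0:
            raise ConfigurationError("seeds_per_fruit_mean must be positive")

    def require_species(self, label: str) -> None:
        if label not in self.species:
            raise KeyError(f"unknown species {label!r}; configured: {self.species}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        d["grid_extent"] = tuple(d["grid_extent"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["grid_extent"] = list(d["grid_extent"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


#: Layer along which the default species niches are spaced.
GRADIENT_LAYER = "temp_north"


def default_scenario(
    n_species: int = 8,
    n_presences: int = 300,
    rng_seed: int = 0,
) -> ScenarioConfig:
    """The default eight-species study system.

    Species occupy Gaussian niches evenly spaced along the north–south
    temperature gradient, with niche breadth one quarter of the inter-optimum
    spacing, so they form ordered, well-separated latitudinal bands.
    Flowering means are staggered across the season; cross-success
    probabilities carry a mild heterospecific deficit.
    """
    species = [f"species_{i + 1}" for i in range(n_species)]
    lo, hi = 0.0, 100.0  # gradient layer value range
    spacing = (hi - lo) / n_species
    breadth = spacing / 4.0

    optima = {
        sp: {GRADIENT_LAYER: lo + spacing * (i + 0.5)}
        for i, sp in enumerate(species)
    }
    breadths = {sp: {GRADIENT_LAYER: breadth} for sp in species}

    season = 150
    fl_lo, fl_hi = 40.0, 110.0
    fl_step = (fl_hi - fl_lo) / max(n_species - 1, 1)
    return ScenarioConfig(
        species=species,
        niche_optima=optima,
        niche_breadths=breadths,
        n_presences={sp: n_presences for sp in species},
        flowering_mean={sp: fl_lo + i * fl_step for i, sp in enumerate(species)},
        flowering_sd={sp: 10.0 for sp in species},
        season_length=season,
        fruit_prob_within={sp: 0.55 for sp in species},
        fruit_prob_between={sp: 0.45 for sp in species},
        seed_viab_within={sp: 0.80 for sp in species},
        seed_viab_between={sp: 0.70 for sp in species},
        pollen_germ_within={sp: 0.60 for sp in species},
        pollen_germ_between={sp: 0.55 for sp in species},
        seeds_per_fruit_mean=20.0,
        rng_seed=rng_seed,
    )
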