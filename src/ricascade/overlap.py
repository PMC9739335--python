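"""Schoener's D overlap in geographic and phenological space.

D(p_X, p_Y) = 1 - 1/2 * sum_i |p_X,i - p_Y,i| compares two probability
distributions over the same sites (grid cells) or time bins (season weeks):
0 for disjoint distributions, 1 for identical ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import SuitabilitySurface

_SUM_TOL = 1e-9


class NormalizationError(ValueError):
    """Raised when a surface cannot be normalized (all-zero support)."""


class ContractError(ValueError):
    """Raised when inputs violate the overlap contracts (grids, sources,
    normalization)."""


@dataclass
class PhenologyDistribution:
    """Weekly flowering probability of one species from one data source."""

    species: str
    source: str  # garden | wild
    week_probs: np.ndarray

    def __post_init__(self) -> None:
        self.week_probs = np.asarray(self.week_probs, dtype=float)
        if np.any(self.week_probs < 0):
            raise ContractError("week probabilities must be non-negative")
        if abs(self.week_probs.sum() - 1.0) > _SUM_TOL:
            raise ContractError(
                f"week probabilities sum to {self.week_probs.sum()}, expected 1"
            )


def normalize_surface(surface: SuitabilitySurface) -> SuitabilitySurface:
    """Rescale a suitability surface into a probability distribution over
    valid cells (the p_X,i of the D index).  Idempotent and scale-invariant."""
    vals = surface.valid_values()
    total = np.nansum(vals)
    if not np.isfinite(total) or total <= 0:
        raise NormalizationError(
            f"surface for {surface.species!r} has no positive valid cells"
        )
    values = np.where(surface.grid.mask, surface.values / total, np.nan)
    return SuitabilitySurface(
        species=surface.species, values=values, grid=surface.grid, normalized=True
    )


def _as_distribution(x) -> np.ndarray:
    if isinstance(x, SuitabilitySurface):
        if not x.normalized:
            raise ContractError(
                f"surface for {x.species!r} is not normalized; call normalize_surface"
            )
        return np.nan_to_num(x.valid_values())
    if isinstance(x, PhenologyDistribution):
        return x.week_probs
    return np.asarray(x, dtype=float)


def schoener_d(pX, pY) -> float:
    """Schoener's D between two distributions on a common grid of sites or
    weeks.  Accepts normalized surfaces, phenology distributions, or arrays."""
    a, b = _as_distribution(pX), _as_distribution(pY)
    if a.shape != b.shape:
        raise ContractError(f"distribution shapes differ: {a.shape} vs {b.shape}")
    for name, v in (("first", a), ("second", b)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ContractError(f"{name} input sums to {v.sum():.6g}, expected 1")
    d = 1.0 - 0.5 * np.abs(a - b).sum()
    return float(min(1.0, max(0.0, d)))  # guard float drift at the endpoints


def phenology_distribution(
    records: pd.DataFrame,
    species: str,
    source: str,
    week_length_days: int = 7,
    n_weeks: int | None = None,
    trim_quantile: float = 0.0,
) -> PhenologyDistribution:
    """Bin a species' flowering-onset days into weekly probabilities.

    Weeks are aligned to season day 1 (day d falls in week ``(d-1) //
    week_length_days``); a final partial week is its own bin.  ``n_weeks``
    fixes a common grid across species; by default the grid spans the weeks
    observed in ``records`` as a whole (all species, same source), so
    distributions built from one records table are directly comparable.
    ``trim_quantile`` optionally drops the most extreme onset dates
    symmetrically (outlier removal for wild observations); default off.
    """
    if not 0.0 <= trim_quantile < 0.5:
        raise ValueError("trim_quantile must be in [0, 0.5)")
    pool = records[records["source"] == source]
    mine = pool[pool["species"] == species]
    if mine.empty:
        raise ValueError(f"no {source!r} flowering records for species {species!r}")
    days = mine["onset_day"].to_numpy()
    if trim_quantile > 0 and len(days) > 2:
        lo, hi = np.quantile(days, [trim_quantile, 1 - trim_quantile])
        kept = days[(days >= lo) & (days <= hi)]
        if len(kept) > 0:
            days = kept
    if n_weeks is None:
        n_weeks = int((pool["onset_day"].max() - 1) // week_length_days) + 1
    weeks = (days - 1) // week_length_days
    if weeks.max() >= n_weeks:
        raise ValueError(
            f"onset days of {species!r} exceed the {n_weeks}-week grid"
        )
    counts = np.bincount(weeks.astype(int), minlength=n_weeks).astype(float)
    return PhenologyDistribution(species=species, source=source, week_probs=counts / counts.sum())


def phenology_overlap(a: PhenologyDistribution, b: PhenologyDistribution) -> float:
    """Schoener's D between two weekly flowering distributions.

    Garden and wild records are never pooled or compared across sources."""
    if a.source != b.source:
        raise ContractError(
            f"cannot compare phenology across sources ({a.source!r} vs {b.source!r})"
        )
    if a.week_probs.shape != b.week_probs.shape:
        raise ContractError("phenology distributions are on different week grids")
    return schoener_d(a, b)


def d_matrix(distributions: dict[str, "PhenologyDistribution | SuitabilitySurface"],
             species_order: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Schoener's D matrix (1.00 diagonal) over a set of species."""
    order = species_order or list(distributions)
    mat = pd.DataFrame(np.eye(len(order)), index=order, columns=order)
    for i, si in enumerate(order):
        for sj in order[i + 1:]:
            a, b = distributions[si], distributions[sj]
            if isinstance(a, PhenologyDistribution):
                d = phenology_overlap(a, b)
            else:
                d = schoener_d(a, b)
            mat.loc[si, sj] = mat.loc[sj, si] = d
    return mat
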