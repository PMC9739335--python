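"""Per-barrier reproductive-isolation (RI) indices for directed species pairs.

Symmetric pre-pollination barriers come from overlap: RI = 1 - D, for both
eco-geographic and phenological overlap.  Asymmetric barriers come from
cross-experiment counts via the relative heterospecific success,
RI = 1 - 2 * between / (within + between), applied to pollen-germination
fractions (Gw, Gb), fruit-set proportions (Pw, Pb), and viable-seed
proportions.  RI = 1 is complete isolation, 0 none, and negative values mean
heterospecific crosses outperform conspecific ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

#: Fixed order in which the barriers act on gene flow.
BARRIER_ORDER = [
    "ecogeography",
    "phenology",
    "pollen_stigma",
    "fruit_set",
    "seed_viability",
]

#: Marker for a barrier that could not be observed for a pair.
MISSING = None


class SchemaError(ValueError):
    """Raised when input tables disagree on species labels or columns."""


@dataclass
class BarrierSeries:
    """Ordered per-barrier RI values for one directed pair (acceptor <- donor).

    ``values`` follows :data:`BARRIER_ORDER`; unobservable barriers hold
    :data:`MISSING` (None).
    """

    acceptor: str
    donor: str
    values: list[tuple[str, float | None]] = field(default_factory=list)
    phenology_source: str = "garden"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.values]
        if names != BARRIER_ORDER[: len(names)]:
            raise ValueError(f"barriers out of order: {names}")

    def ri_values(self) -> list[float | None]:
        return [v for _, v in self.values]


class CrossSummary(NamedTuple):
    """Pooled within/between success fractions for one directed pair.

    Fields are None where the underlying counts are inadequate (fewer than
    ``min_n`` records) or absent.
    """

    gw: float | None  # within-species pollen germination fraction
    gb: float | None  # between-species pollen germination fraction
    pw_fruit: float | None
    pb_fruit: float | None
    pw_seed: float | None
    pb_seed: float | None


def ri_from_overlap(d: float) -> float:
    """RI of a symmetric overlap barrier: 1 - D."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"overlap D={d} outside [0, 1]")
    return 1.0 - d


def ri_asymmetric(within: float, between: float) -> float | None:
    """RI from within/between success measures: 1 - 2 b / (w + b).

    Equals 1 when heterospecific success is zero, 0 when equal, and -1 when
    conspecific success is zero (heterospecific advantage).  Returns MISSING
    with a warning when both successes are zero (barrier unobservable).
    """
    if within < 0 or between < 0:
        raise ValueError("success measures must be non-negative")
    if within + between == 0:
        warnings.warn(
            "within and between success both zero; barrier unobservable",
            stacklevel=2,
        )
        return MISSING
    return 1.0 - 2.0 * between / (within + between)


def _pooled_fraction(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def cross_summaries(
    records: pd.DataFrame,
    acceptor: str,
    donor: str,
    min_n: int = 5,
    pool_donors: bool = True,
) -> CrossSummary:
    """Pooled success fractions for a directed pair from a crosses table.

    Fractions are ratios of pooled counts (germinated/total pollen,
    fruits/pollinations, viable/total seeds), never means of per-flower
    ratios.  A treatment x pair cell with fewer than ``min_n`` pollination
    records is treated as unobserved.  With ``pool_donors`` (default), the
    "between" fractions pool every donor whose pair individually meets
    ``min_n`` — but the requested pair itself must also meet ``min_n`` for
    the result to be non-missing.
    """
    recs = records[records["acceptor"] == acceptor]
    if recs.empty:
        return CrossSummary(None, None, None, None, None, None)
    within = recs[recs["treatment"] == "within"]
    between = recs[recs["treatment"] == "between"]
    pair = between[between["donor"] == donor]

    def fracs(df: pd.DataFrame) -> tuple[float | None, float | None, float | None]:
        if df.empty or df["n_pollinations"].sum() < min_n:
            return None, None, None
        pollen = df.dropna(subset=["n_pollen_total"])
        g = _pooled_fraction(
            int(pollen["n_pollen_germinated"].sum()), int(pollen["n_pollen_total"].sum())
        ) if not pollen.empty else None
        fruit = _pooled_fraction(int(df["n_fruits"].sum()), int(df["n_pollinations"].sum()))
        seed = _pooled_fraction(int(df["n_seeds_viable"].sum()), int(df["n_seeds_total"].sum()))
        return g, fruit, seed

    gw, pw_fruit, pw_seed = fracs(within)
    if pair.empty or pair["n_pollinations"].sum() < min_n:
        # the requested pair itself lacks adequate between-cross data
        return CrossSummary(gw, None, pw_fruit, None, pw_seed, None)
    if pool_donors:
        ok_donors = [
            d for d, grp in between.groupby("donor")
            if grp["n_pollinations"].sum() >= min_n
        ]
        gb, pb_fruit, pb_seed = fracs(between[between["donor"].isin(ok_donors)])
    else:
        gb, pb_fruit, pb_seed = fracs(pair)
    return CrossSummary(gw, gb, pw_fruit, pb_fruit, pw_seed, pb_seed)


def _pair_asymmetric(summary: CrossSummary) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for name, w, b in (
        ("pollen_stigma", summary.gw, summary.gb),
        ("fruit_set", summary.pw_fruit, summary.pb_fruit),
        ("seed_viability", summary.pw_seed, summary.pb_seed),
    ):
        out[name] = MISSING if w is None or b is None else ri_asymmetric(w, b)
    return out


def assemble_barriers(
    d_eco: pd.DataFrame,
    d_phen: pd.DataFrame,
    crosses: pd.DataFrame | None,
    species: list[str],
    phenology_source: str = "garden",
    min_n: int = 5,
    pool_donors: bool = True,
) -> list[BarrierSeries]:
    """One :class:`BarrierSeries` per ordered species pair (n*(n-1) series).

    Symmetric barriers (eco-geography, phenology) are filled for every pair
    from the D matrices; asymmetric barriers only where the acceptor has
    adequate cross data, else MISSING — partial sequences are the normal case
    when only a subset of species served as pollen acceptors.
    """
    for name, mat in (("eco", d_eco), ("phenology", d_phen)):
        miss = set(species) - set(mat.index) | set(species) - set(mat.columns)
        if miss:
            raise SchemaError(f"{name} D matrix lacks species {sorted(miss)}")
    series: list[BarrierSeries] = []
    for acc in species:
        for don in species:
            if acc == don:
                continue
            vals: list[tuple[str, float | None]] = [
                ("ecogeography", ri_from_overlap(float(d_eco.loc[acc, don]))),
                ("phenology", ri_from_overlap(float(d_phen.loc[acc, don]))),
            ]
            if crosses is None or crosses.empty:
                asym = {n: MISSING for n in BARRIER_ORDER[2:]}
            else:
                unknown = set(crosses["acceptor"]) | set(crosses["donor"])
                unknown -= set(species)
                if unknown:
                    raise SchemaError(f"cross table has unknown species {sorted(unknown)}")
                asym = _pair_asymmetric(
                    cross_summaries(crosses, acc, don, min_n=min_n, pool_donors=pool_donors)
                )
            vals += [(n, asym[n]) for n in BARRIER_ORDER[2:]]
            series.append(
                BarrierSeries(acceptor=acc, donor=don, values=vals,
                              phenology_source=phenology_source)
            )
    return series


def barriers_to_frame(series: list[BarrierSeries]) -> pd.DataFrame:
    """Long-format table: acceptor, donor, barrier, value, missing_flag, source."""
    rows = []
    for s in series:
        for name, v in s.values:
            rows.append({
                "acceptor": s.acceptor,
                "donor": s.donor,
                "barrier": name,
                "value": math.nan if v is MISSING else v,
                "missing_flag": v is MISSING,
                "phenology_source": s.phenology_source,
            })
    return pd.DataFrame(rows)
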