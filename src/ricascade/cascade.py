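"""Sequential composition of barrier strengths into total reproductive isolation.

Barriers act in a fixed order on the gene flow that earlier barriers let
through.  The absolute contribution of barrier n is

    AC_n = RI_n * (1 - sum_{i<n} AC_i)

and total isolation is T = sum_n AC_n, which equals 1 - prod_n (1 - RI_n)
when every barrier is observed.  An unobserved (MISSING) barrier contributes
0 and leaves the remaining gene flow untouched, so partially observed pairs
compose only their tested barriers.  Negative RI values (heterospecific
advantage) propagate unchanged and can reduce T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barriers import BARRIER_ORDER, MISSING, BarrierSeries


@dataclass
class RICascade:
    """Absolute contributions and total RI for one directed pair."""

    acceptor: str
    donor: str
    ac_values: list[float] = field(default_factory=list)
    missing_flags: list[bool] = field(default_factory=list)
    total: float = 0.0
    phenology_source: str = "garden"


def absolute_contributions(ri_values: list[float | None]) -> list[float]:
    """Absolute contribution of each barrier given ordered RI values.

    AC_1 = RI_1; AC_n = RI_n * (1 - sum of earlier ACs).  MISSING entries
    yield AC = 0 without consuming remaining gene flow.
    """
    if not ri_values:
        raise ValueError("need at least one barrier RI value")
    acs: list[float] = []
    remaining = 1.0
    for ri in ri_values:
        if ri is MISSING or (isinstance(ri, float) and math.isnan(ri)):
            acs.append(0.0)
            continue
        if not -1.0 <= ri <= 1.0:
            raise ValueError(f"RI value {ri} outside [-1, 1]")
        ac = ri * remaining
        acs.append(ac)
        remaining -= ac
    return acs


def total_ri(ac_values: list[float]) -> float:
    """Total RI: the sum of absolute contributions of all tested barriers."""
    if not ac_values:
        raise ValueError("need at least one absolute contribution")
    return float(sum(ac_values))


def compose(series: BarrierSeries) -> RICascade:
    """Run the cascade for one directed pair's barrier series."""
    ris = series.ri_values()
    acs = absolute_contributions(ris)
    return RICascade(
        acceptor=series.acceptor,
        donor=series.donor,
        ac_values=acs,
        missing_flags=[r is MISSING for r in ris],
        total=total_ri(acs),
        phenology_source=series.phenology_source,
    )


def build_ri_table(
    cascades_garden: list[RICascade],
    cascades_wild: list[RICascade],
    species_order: list[str],
    decimals: int | None = None,
) -> pd.DataFrame:
    """Paired total-RI matrix: rows are acceptors; cells above the diagonal
    hold garden-phenology totals, below the diagonal wild-phenology totals,
    and the diagonal is blank.

    ``decimals`` rounds for display (half-up); by default full precision is
    retained.
    """
    def index(cascades: list[RICascade]) -> dict[tuple[str, str], float]:
        return {(c.acceptor, c.donor): c.total for c in cascades}

    garden, wild = index(cascades_garden), index(cascades_wild)
    n = len(species_order)
    mat = pd.DataFrame(np.full((n, n), np.nan), index=species_order, columns=species_order)
    for i, acc in enumerate(species_order):
        for j, don in enumerate(species_order):
            if i == j:
                continue
            source = garden if i < j else wild
            if (acc, don) not in source:
                raise ValueError(f"no cascade for directed pair {acc!r} -> {don!r}")
            v = source[(acc, don)]
            if decimals is not None:
                v = _round_half_up(v, decimals)
            mat.iloc[i, j] = v
    return mat


def _round_half_up(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


def cascades_to_frame(cascades: list[RICascade],
                      series: list[BarrierSeries] | None = None) -> pd.DataFrame:
    """Long-format cascade table: acceptor, donor, barrier, RI, AC,
    missing_flag, source.  RI columns require the matching barrier series."""
    ri_lookup = {}
    if series is not None:
        ri_lookup = {(s.acceptor, s.donor): s.ri_values() for s in series}
    rows = []
    for c in cascades:
        ris = ri_lookup.get((c.acceptor, c.donor), [math.nan] * len(c.ac_values))
        for name, ac, miss, ri in zip(BARRIER_ORDER, c.ac_values, c.missing_flags, ris):
            rows.append({
                "acceptor": c.acceptor,
                "donor": c.donor,
                "barrier": name,
                "ri": math.nan if ri is MISSING else ri,
                "ac": ac,
                "missing_flag": miss,
                "phenology_source": c.phenology_source,
            })
    return pd.DataFrame(rows)


def relative_contributions(cascades: list[RICascade]) -> pd.DataFrame:
    """Stacked-contribution summary: each barrier's share AC_n / T per pair
    (NaN when T = 0), the quantity behind 'which barrier drives isolation'."""
    rows = []
    for c in cascades:
        for name, ac in zip(BARRIER_ORDER, c.ac_values):
            rows.append({
                "acceptor": c.acceptor,
                "donor": c.donor,
                "barrier": name,
                "relative_contribution": ac / c.total if c.total != 0 else math.nan,
                "phenology_source": c.phenology_source,
            })
    return pd.DataFrame(rows)
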