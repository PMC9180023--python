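"""Theil index and its between-/within-zone decomposition.

The index used here is the measure-weighted mean log deviation of measure
shares against resource shares:

    T_total = sum_i (m_i/M) ln( (m_i/M) / (e_i/E) )

with m_i the calibre measure (population or area) and e_i the resource
quantity of region i.  T_total = 0 iff every region's resource share equals
its measure share; it grows without bound as some region's resources vanish
relative to its measure (hence zero-resource regions are a hard error — the
log diverges and no silent epsilon is defensible).

Because the index is additively decomposable, grouping regions into zones
splits it exactly:

    T_total = T_inter + T_intra
    T_inter = sum_g (M_g/M) ln( (M_g/M) / (E_g/E) )
    T_intra = sum_g (M_g/M) T_g,   T_g = sum_{i in g} (m_i/M_g) ln( (m_i/M_g) / (e_i/E_g) )

T_inter measures inequity between zone totals, T_intra the measure-weighted
inequity inside zones.  Contribution rates T_intra/T_total and
T_inter/T_total attribute the total inequity to the two levels.

Natural logarithms throughout; contribution rates are ratios of Theils and
therefore base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ZeroResourceError
from .panel import (
    AllocationVector,
    Calibre,
    ResourceKind,
    ResourcePanel,
    Tier,
    VALID_COMBOS,
)


@dataclass(frozen=True)
class TheilDecomposition:
    T_total: float
    T_inter: float
    T_intra: float
    #: zone -> (within-zone Theil T_g, weight M_g/M), zones in first-appearance order
    per_zone: dict[str, tuple[float, float]]
    contrib_intra: float
    contrib_inter: float
    calibre: Calibre
    tier: Tier | None = None
    kind: ResourceKind | None = None
    year: int | None = None


def _check_positive_resources(alloc: AllocationVector) -> None:
    zero = np.asarray(alloc.e) == 0
    if zero.any():
        rid = alloc.region_ids[int(np.argmax(zero))]
        raise ZeroResourceError(
            f"region {rid!r} has zero resources; Theil log term diverges "
            "(filter such regions explicitly if exclusion is intended)"
        )


def _mld(w: np.ndarray, s: np.ndarray) -> float:
    """Weighted mean log deviation sum w ln(w/s); w, s are share vectors."""
    return float(np.sum(w * np.log(w / s)))


def theil_total(alloc: AllocationVector) -> float:
    """Total Theil index of a cross-section (natural log)."""
    _check_positive_resources(alloc)
    return _mld(alloc.measure_shares, alloc.resource_shares)


def theil_decompose(alloc: AllocationVector) -> TheilDecomposition:
    """Exact between-/within-zone split of the total Theil index."""
    _check_positive_resources(alloc)
    w = alloc.measure_shares
    s = alloc.resource_shares
    T_total = _mld(w, s)

    groups = alloc.aggregate_zones()  # (zone, M_g, E_g)
    M = alloc.m.sum()
    E = alloc.e.sum()

    zones = np.asarray(alloc.zones)
    T_inter = 0.0
    T_intra = 0.0
    per_zone: dict[str, tuple[float, float]] = {}
    for zone, Mg, Eg in groups:
        wg = Mg / M
        sg = Eg / E
        T_inter += wg * np.log(wg / sg)
        mask = zones == zone
        # zone-internal shares
        T_g = _mld(alloc.m[mask] / Mg, alloc.e[mask] / Eg)
        per_zone[zone] = (T_g, wg)
        T_intra += wg * T_g

    if T_total > 0:
        contrib_intra = T_intra / T_total
        contrib_inter = T_inter / T_total
    else:  # perfectly proportional: all inequity (none) is within-zone
        contrib_intra, contrib_inter = 1.0, 0.0

    return TheilDecomposition(
        T_total=T_total,
        T_inter=float(T_inter),
        T_intra=float(T_intra),
        per_zone=per_zone,
        contrib_intra=float(contrib_intra),
        contrib_inter=float(contrib_inter),
        calibre=alloc.calibre,
        tier=alloc.tier,
        kind=alloc.kind,
        year=alloc.year,
    )


def theil_series(
    panel: ResourcePanel,
    tier: Tier,
    kind: ResourceKind,
    calibre: Calibre = Calibre.POPULATION,
) -> list[TheilDecomposition]:
    """Yearly Theil decompositions, ascending year order.

    Population is the default calibre for Theil reporting; geography is
    available for symmetry with the Gini analysis.
    """
    return [
        theil_decompose(panel.slice_allocation(year, tier, kind, calibre))
        for year in panel.years
    ]


# ---------------------------------------------------------------------------
# contribution-rate table (within-zone share of total inequity, by year)
# ---------------------------------------------------------------------------

def combo_label(tier: Tier, kind: ResourceKind) -> str:
    return f"{tier.value}_{kind.value}"


def format_contribution_table(yearly: pd.DataFrame) -> pd.DataFrame:
    """Round a table of yearly contribution percentages and append the mean row.

    ``yearly`` is indexed by year with one column per (tier, kind) series,
    values in percent.  Yearly cells are rounded to 2 decimals; the final
    ``mean`` row is the arithmetic mean of the rounded yearly values, itself
    rounded to 2 decimals — the convention published tables of this kind use.
    """
    rounded = yearly.astype(float).round(2)
    mean_row = rounded.mean(axis=0).round(2)
    mean_row.name = "mean"
    out = pd.concat([rounded, mean_row.to_frame().T])
    out.index.name = "year"
    return out


def contribution_table(
    panel: ResourcePanel, calibre: Calibre = Calibre.POPULATION
) -> pd.DataFrame:
    """Within-zone contribution rates (percent) per year x (tier, kind).

    One row per year, eight columns (CMHI x 3 kinds, TH x 3, VC x 2), each
    cell 100 * T_intra/T_total, plus a final arithmetic-mean row.
    """
    data: dict[str, list[float]] = {}
    for tier, kind in VALID_COMBOS:
        series = theil_series(panel, tier, kind, calibre)
        data[combo_label(tier, kind)] = [100.0 * d.contrib_intra for d in series]
    yearly = pd.DataFrame(data, index=pd.Index(panel.years, name="year"))
    return format_contribution_table(yearly)
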