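"""Health resource density index (HRDI).

A per-capita density ignores that sparse, vast regions need resources
spread over space; a per-area density ignores population load.  The HRDI
balances the two by normalising the resource quantity HR by the geometric
mean of population and area:

    HRDI = HR / sqrt((A / area_unit) * (P / pop_unit))

Display units are configurable; the defaults report resources per
sqrt(1000 persons x 1 km^2).  The index is share-free, so unlike the Gini
and Theil indices its numeric scale depends on these units.

At zone or national level the quantities are summed first and the formula
applied to the sums — the aggregate HRDI is *not* the mean of member HRDIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EquipanelError, YearRangeError
from .panel import (
    ResourceKind,
    ResourcePanel,
    Tier,
    VALID_COMBOS,
    resource_column,
)

#: Default display units: population in thousands of persons, area in km^2.
DEFAULT_POP_UNIT = 1_000.0
DEFAULT_AREA_UNIT = 1.0


@dataclass(frozen=True)
class HRDIResult:
    scope: str        # region_id, zone label, or "national"
    level: str        # "province" | "zone" | "national"
    tier: Tier
    kind: ResourceKind
    year: int
    hrdi: float


def hrdi(
    resource: float,
    area: float,
    population: float,
    pop_unit: float = DEFAULT_POP_UNIT,
    area_unit: float = DEFAULT_AREA_UNIT,
) -> float:
    """HRDI of one scope: HR / sqrt((A/area_unit) * (P/pop_unit))."""
    if resource < 0:
        raise EquipanelError("resource quantity must be non-negative")
    if area <= 0 or population <= 0 or pop_unit <= 0 or area_unit <= 0:
        raise EquipanelError("area, population and units must be positive")
    return resource / math.sqrt((area / area_unit) * (population / pop_unit))


def hrdi_table(
    panel: ResourcePanel,
    year: int,
    level: str = "province",
    pop_unit: float = DEFAULT_POP_UNIT,
    area_unit: float = DEFAULT_AREA_UNIT,
) -> list[HRDIResult]:
    """HRDI of every (scope, tier, kind) at the requested aggregation level.

    level "province" gives one row per region; "zone" sums population, area
    and resources over zone members before applying the formula; "national"
    likewise over the whole panel.
    """
    if level not in ("province", "zone", "national"):
        raise EquipanelError(f"unknown aggregation level {level!r}")
    lo, hi = panel.year_range
    if not lo <= year <= hi:
        raise YearRangeError(f"year {year} outside panel range [{lo}, {hi}]")

    df = panel.frame
    sub = df[df["year"] == year].sort_values("region_id")

    if level == "province":
        groups = [(str(r["region_id"]), r) for _, r in sub.iterrows()]
        sums = [
            (scope, r["population"], r["area_km2"], r)
            for scope, r in groups
        ]
    else:
        if level == "zone":
            keys = [(z, sub[sub["zone"] == z]) for z in panel.zones]
        else:
            keys = [("national", sub)]
        sums = [
            (scope, g["population"].sum(), g["area_km2"].sum(), g.sum(numeric_only=True))
            for scope, g in keys
        ]

    out: list[HRDIResult] = []
    for scope, pop, area, row in sums:
        for tier, kind in VALID_COMBOS:
            hr = float(row[resource_column(tier, kind)])
            out.append(
                HRDIResult(
                    scope=scope,
                    level=level,
                    tier=tier,
                    kind=kind,
                    year=year,
                    hrdi=hrdi(hr, float(area), float(pop), pop_unit, area_unit),
                )
            )
    return out


def hrdi_series(
    panel: ResourcePanel,
    pop_unit: float = DEFAULT_POP_UNIT,
    area_unit: float = DEFAULT_AREA_UNIT,
) -> pd.DataFrame:
    """Zone + national HRDI for every year x (tier, kind).

    Long-format frame with columns scope, level, tier, kind, year, hrdi —
    the data behind per-zone trend curves and the choropleth source tables.
    """
    rows = []
    for year in panel.years:
        for level in ("zone", "national"):
            rows.extend(hrdi_table(panel, year, level, pop_unit, area_unit))
    return pd.DataFrame(
        [
            {
                "scope": r.scope,
                "level": r.level,
                "tier": r.tier.value,
                "kind": r.kind.value,
                "year": r.year,
                "hrdi": r.hrdi,
            }
            for r in rows
        ]
    )
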