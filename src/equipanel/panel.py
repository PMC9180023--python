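"""Region-year resource panels for a tiered healthcare system.

The data model is a *balanced* panel of administrative regions observed
annually: each region carries a population, a land area, an economic-zone
label, and non-negative resource counts for every valid (facility tier,
resource kind) combination.  The three facility tiers follow China's rural
three-tier network — county-level medical and health institutions (CMHI),
township hospitals (TH) and village clinics (VC) — and the three resource
kinds are institutions, beds and personnel.  Village clinics carry no beds,
so the panel has 8 resource columns, not 9.

All downstream indices consume single-year cross-sections
(:class:`AllocationVector`): per-region pairs of a *measure* m_i (population
or area, selected by the calibre) and a resource quantity e_i.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    PanelValidationError,
    SchemaError,
    UnsupportedCombinationError,
    YearRangeError,
)


class Tier(str, enum.Enum):
    """Facility tier of the three-tier rural network."""

    CMHI = "cmhi"  # county-level medical and health institutions
    TH = "th"      # township hospitals
    VC = "vc"      # village clinics


class ResourceKind(str, enum.Enum):
    """Resource kind: institutions and beds are capital, personnel is labour."""

    INSTITUTION = "institution"
    BED = "bed"
    PERSONNEL = "personnel"


class Calibre(str, enum.Enum):
    """Weighting base for shares: population or geographic area."""

    POPULATION = "population"
    GEOGRAPHY = "geography"


#: Default three-zone scheme (eastern/central/western economic zones).
DEFAULT_ZONES = ("eastern", "central", "western")

#: The 8 valid (tier, kind) combinations — village clinics have no beds.
VALID_COMBOS: tuple[tuple[Tier, ResourceKind], ...] = tuple(
    (t, k)
    for t in Tier
    for k in ResourceKind
    if not (t is Tier.VC and k is ResourceKind.BED)
)


def resource_column(tier: Tier, kind: ResourceKind) -> str:
    """CSV column name for a (tier, kind) combination, e.g. ``cmhi_bed``."""
    if tier is Tier.VC and kind is ResourceKind.BED:
        raise UnsupportedCombinationError("village clinics carry no beds")
    return f"{tier.value}_{kind.value}"


ID_COLUMNS = ["region_id", "zone", "year", "population", "area_km2"]
RESOURCE_COLUMNS = [resource_column(t, k) for t, k in VALID_COMBOS]
ALL_COLUMNS = ID_COLUMNS + RESOURCE_COLUMNS


@dataclass(frozen=True)
class RegionYearRecord:
    """One region observed in one year."""

    region_id: str
    zone: str
    year: int
    population: float
    area: float
    resources: dict[tuple[Tier, ResourceKind], float]

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise PanelValidationError(
                f"population must be > 0 for ({self.region_id}, {self.year})"
            )
        if self.area <= 0:
            raise PanelValidationError(
                f"area must be > 0 for ({self.region_id}, {self.year})"
            )
        for (tier, kind), v in self.resources.items():
            if tier is Tier.VC and kind is ResourceKind.BED:
                raise PanelValidationError(
                    f"(VC, bed) resource present for ({self.region_id}, {self.year})"
                )
            if v < 0:
                raise PanelValidationError(
                    f"negative {tier.value}_{kind.value} for "
                    f"({self.region_id}, {self.year})"
                )


class ResourcePanel:
    """Validated balanced panel of region-year records.

    Internally a :class:`pandas.DataFrame` in the canonical column order,
    sorted by (region_id, year) so every fixed-order summation downstream is
    reproducible regardless of input row order.

    Parameters
    ----------
    data : DataFrame
        Long-format table with columns ``region_id, zone, year, population,
        area_km2`` plus one column per valid (tier, kind).
    metadata : dict, optional
        Free-form provenance (e.g. generator config hash); carried along,
        never interpreted.
    """

    def __init__(self, data: pd.DataFrame, metadata: dict | None = None):
        self._df = _validate_frame(data)
        self.metadata = dict(metadata or {})

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[RegionYearRecord]) -> "ResourcePanel":
        rows = []
        for r in records:
            row = {
                "region_id": r.region_id,
                "zone": r.zone,
                "year": r.year,
                "population": r.population,
                "area_km2": r.area,
            }
            for (tier, kind) in VALID_COMBOS:
                row[resource_column(tier, kind)] = r.resources.get((tier, kind), 0.0)
            rows.append(row)
        return cls(pd.DataFrame(rows))

    # -- basic properties --------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The validated table (copy)."""
        return self._df.copy()

    @property
    def regions(self) -> list[str]:
        """Region ids in canonical (lexicographic) order."""
        return sorted(self._df["region_id"].unique())

    @property
    def zones(self) -> list[str]:
        """Zone labels in order of first appearance along canonical region order."""
        seen: dict[str, None] = {}
        sub = self._df.drop_duplicates("region_id").sort_values("region_id")
        for z in sub["zone"]:
            seen.setdefault(z, None)
        return list(seen)

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self._df["year"].unique())

    @property
    def year_range(self) -> tuple[int, int]:
        ys = self.years
        return ys[0], ys[-1]

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResourcePanel):
            return NotImplemented
        return self._df.equals(other._df)

    # -- slicing -----------------------------------------------------------

    def slice_allocation(
        self, year: int, tier: Tier, kind: ResourceKind, calibre: Calibre
    ) -> "AllocationVector":
        """Single-year cross-section feeding the Lorenz/Gini/Theil formulas.

        m_i is the population (population calibre) or land area (geography
        calibre) of region i; e_i the resource count for (tier, kind).
        """
        if tier is Tier.VC and kind is ResourceKind.BED:
            raise UnsupportedCombinationError("village clinics carry no beds")
        lo, hi = self.year_range
        if not lo <= year <= hi:
            raise YearRangeError(f"year {year} outside panel range [{lo}, {hi}]")
        sub = self._df[self._df["year"] == year].sort_values("region_id")
        mcol = "population" if calibre is Calibre.POPULATION else "area_km2"
        return AllocationVector(
            region_ids=tuple(sub["region_id"]),
            zones=tuple(sub["zone"]),
            m=np.asarray(sub[mcol], dtype=float),
            e=np.asarray(sub[resource_column(tier, kind)], dtype=float),
            calibre=calibre,
            tier=tier,
            kind=kind,
            year=year,
        )


@dataclass(frozen=True)
class AllocationVector:
    """A single-year cross-section for one (tier, kind, calibre).

    Entries are in canonical region order.  ``m`` is the measure (population
    or area), ``e`` the resource quantity; both as float arrays.
    """

    region_ids: tuple[str, ...]
    zones: tuple[str, ...]
    m: np.ndarray
    e: np.ndarray
    calibre: Calibre
    tier: Tier | None = None
    kind: ResourceKind | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "e", e)
        if len({len(self.region_ids), len(self.zones), m.size, e.size}) != 1:
            raise PanelValidationError("allocation fields have mismatched lengths")
        if m.size == 0:
            raise PanelValidationError("allocation vector is empty")
        if not np.all(m > 0):
            raise PanelValidationError("all measures m_i must be > 0")
        if not np.all(e >= 0):
            raise PanelValidationError("all resource quantities e_i must be >= 0")

    @property
    def n(self) -> int:
        return self.m.size

    @property
    def measure_shares(self) -> np.ndarray:
        return self.m / self.m.sum()

    @property
    def resource_shares(self) -> np.ndarray:
        total = self.e.sum()
        if total <= 0:
            from .errors import DegenerateAllocationError

            raise DegenerateAllocationError(
                "all resource quantities are zero; shares undefined"
            )
        return self.e / total

    def aggregate_zones(self) -> list[tuple[str, float, float]]:
        """Zone-level totals (zone, M_g, E_g), in order of first appearance.

        Zone sums use exact (fsum) accumulation over the fixed canonical
        region order, so sum_g M_g recovers sum_i m_i to regrouping
        round-off (a couple of ulp), independent of zone labelling.
        """
        import math

        order: dict[str, list[int]] = {}
        for i, z in enumerate(self.zones):
            order.setdefault(z, []).append(i)
        return [
            (
                z,
                math.fsum(self.m[i] for i in idx),
                math.fsum(self.e[i] for i in idx),
            )
            for z, idx in order.items()
        ]


# ---------------------------------------------------------------------------
# validation and file I/O
# ---------------------------------------------------------------------------

def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    # (VC, bed) handled separately: must be absent OR all-zero/empty
    vc_bed = "vc_bed"
    if vc_bed in df.columns:
        col = pd.to_numeric(df[vc_bed], errors="coerce").fillna(0)
        if (col != 0).any():
            raise PanelValidationError(
                "vc_bed column present and non-empty: village clinics carry no beds"
            )
        df = df.drop(columns=[vc_bed])
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df[ALL_COLUMNS].copy()
    df["region_id"] = df["region_id"].astype(str)
    df["zone"] = df["zone"].astype(str)
    df["year"] = df["year"].astype(int)
    for c in ["population", "area_km2"] + RESOURCE_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise").astype(float)

    bad = df[(df["population"] <= 0) | (df["area_km2"] <= 0)]
    if len(bad):
        r = bad.iloc[0]
        raise PanelValidationError(
            f"non-positive population/area for ({r['region_id']}, {int(r['year'])})"
        )
    neg = df[(df[RESOURCE_COLUMNS] < 0).any(axis=1)]
    if len(neg):
        r = neg.iloc[0]
        raise PanelValidationError(
            f"negative resource count for ({r['region_id']}, {int(r['year'])})"
        )

    dup = df.duplicated(subset=["region_id", "year"])
    if dup.any():
        r = df[dup].iloc[0]
        raise PanelValidationError(
            f"duplicate (region_id, year) = ({r['region_id']}, {int(r['year'])})"
        )

    # zone must be constant per region
    nz = df.groupby("region_id")["zone"].nunique()
    if (nz > 1).any():
        raise PanelValidationError(
            f"region {nz[nz > 1].index[0]!r} mapped to more than one zone"
        )

    # balanced panel: every region present in every year
    years = sorted(df["year"].unique())
    counts = df.groupby("region_id")["year"].nunique()
    if (counts != len(years)).any():
        rid = counts[counts != len(years)].index[0]
        raise PanelValidationError(
            f"unbalanced panel: region {rid!r} missing in some years of "
            f"[{years[0]}, {years[-1]}]"
        )

    return df.sort_values(["region_id", "year"]).reset_index(drop=True)


def load_panel(path) -> ResourcePanel:
    """Read a panel from CSV (UTF-8, header row) and validate it.

    Row order in the file is irrelevant: records are re-sorted into
    canonical (region_id, year) order, so shuffled files give identical
    panels and identical downstream results.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except (pd.errors.ParserError, ValueError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    return ResourcePanel(df)


def write_panel(panel: ResourcePanel, path) -> None:
    """Write a panel back to CSV in the canonical dialect (round-trip safe)."""
    panel.frame.to_csv(path, index=False)
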