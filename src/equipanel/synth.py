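"""Synthetic province-year panels with the structure the analysis assumes.

The generator emulates a country of ~31 provincial units grouped into three
economic zones, observed annually over an 18-year window.  Populations and
areas are lognormal (provincial sizes are positive and right-skewed) and
constant over the window; resource *densities* (resources per person) are
lognormal around a per-(tier, kind) base, shifted by a zone-level log offset
(eastern > central > western by default, matching the east-west gradient of
developed health systems), with independent province-year log noise:

    count_{i,t} = round( base * exp(offset_z + eta_{i,t} + trend * (t - t0)) * pop_i ),
    eta_{i,t} ~ Normal(0, within_sigma + inequality_drift * (t - t0))

Because eta is redrawn independently every year, a configuration with zero
trend and zero inequality drift yields index series that are i.i.d. across
years — the null the trend-test calibration checks run against.

``generate_two_block`` builds two-region allocations whose Gini and Theil
have closed forms (G = |s - p|, T = p ln(p/s) + (1-p) ln((1-p)/(1-s))),
used as cross-module oracles.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, EquipanelError
from .panel import (
    AllocationVector,
    Calibre,
    ResourceKind,
    ResourcePanel,
    Tier,
    VALID_COMBOS,
    resource_column,
)


def _default_zone_sizes() -> dict[str, int]:
    # 11 / 8 / 12 provincial units: the usual east / central / west partition
    return {"eastern": 11, "central": 8, "western": 12}


def _default_density_base() -> dict[tuple[Tier, ResourceKind], float]:
    # resources per person, magnitudes typical of a large middle-income
    # country's rural tiers: few county institutions, ~2-3 beds and
    # personnel per 1000, many village clinics
    return {
        (Tier.CMHI, ResourceKind.INSTITUTION): 1.0e-5,
        (Tier.CMHI, ResourceKind.BED): 2.0e-3,
        (Tier.CMHI, ResourceKind.PERSONNEL): 3.0e-3,
        (Tier.TH, ResourceKind.INSTITUTION): 2.5e-5,
        (Tier.TH, ResourceKind.BED): 8.0e-4,
        (Tier.TH, ResourceKind.PERSONNEL): 1.0e-3,
        (Tier.VC, ResourceKind.INSTITUTION): 4.0e-4,
        (Tier.VC, ResourceKind.PERSONNEL): 1.0e-3,
    }


def _default_zone_offsets() -> dict[str, float]:
    return {"eastern": 0.25, "central": 0.0, "western": -0.25}


def _default_zone_pop_offsets() -> dict[str, float]:
    # east-dense / west-sparse population gradient
    return {"eastern": 0.4, "central": 0.0, "western": -0.3}


def _default_zone_area_offsets() -> dict[str, float]:
    # western provincial units are far larger, eastern ones compact
    return {"eastern": -0.6, "central": 0.0, "western": 0.8}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic panel.

    Parameters
    ----------
    n_provinces_per_zone : zone label -> count (default 11/8/12).
    years : inclusive (first, last) calendar years, default (2003, 2020).
    pop_lognormal : (mu, sigma) of log population in persons; the default
        centres provinces near 3e7 persons with sigma 0.8.
    area_lognormal : (mu, sigma) of log area in km^2, centred near 3e5 km^2.
    density_base : (tier, kind) -> resources per person at zone offset 0.
    zone_offsets : zone -> log-density shift.
    zone_pop_offsets, zone_area_offsets : zone -> shift of the log-population
        and log-area locations, emulating the dense-east / vast-sparse-west
        gradient of the three-zone scheme.
    within_sigma : province-year log-density noise s.d. (default 0.3).
    trend : (tier, kind) -> per-year log-density drift (default all 0:
        stationary null; see ``inject_trend`` for trended variants).
    inequality_drift : per-year growth of the noise s.d. (default 0).
    round_counts : round resources to integers with a floor of 1 where the
        density is positive (yearbook semantics); disable for exactness
        checks.
    """

    n_provinces_per_zone: dict[str, int] = field(default_factory=_default_zone_sizes)
    years: tuple[int, int] = (2003, 2020)
    pop_lognormal: tuple[float, float] = (math.log(3.0e7), 0.8)
    area_lognormal: tuple[float, float] = (math.log(3.0e5), 0.9)
    density_base: dict[tuple[Tier, ResourceKind], float] = field(
        default_factory=_default_density_base
    )
    zone_offsets: dict[str, float] = field(default_factory=_default_zone_offsets)
    zone_pop_offsets: dict[str, float] = field(default_factory=_default_zone_pop_offsets)
    zone_area_offsets: dict[str, float] = field(default_factory=_default_zone_area_offsets)
    within_sigma: float = 0.3
    trend: dict[tuple[Tier, ResourceKind], float] = field(default_factory=dict)
    inequality_drift: float = 0.0
    round_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_provinces_per_zone or any(
            n <= 0 for n in self.n_provinces_per_zone.values()
        ):
            raise ConfigError("each zone needs a positive number of provinces")
        if self.years[1] < self.years[0]:
            raise ConfigError("years must be an increasing range")
        if self.within_sigma < 0 or self.pop_lognormal[1] < 0 or self.area_lognormal[1] < 0:
            raise ConfigError("all sigmas must be non-negative")
        for combo, v in self.density_base.items():
            if combo not in VALID_COMBOS:
                raise ConfigError(f"invalid (tier, kind) combination {combo}")
            if v < 0:
                raise ConfigError("density bases must be non-negative")
        for offsets in (self.zone_offsets, self.zone_pop_offsets, self.zone_area_offsets):
            for z in offsets:
                if z not in self.n_provinces_per_zone:
                    raise ConfigError(f"zone offset for unknown zone {z!r}")

    def hash(self) -> str:
        """Stable short hash of the configuration (recorded in panel metadata)."""
        payload = {
            "zones": sorted(self.n_provinces_per_zone.items()),
            "years": self.years,
            "pop": self.pop_lognormal,
            "area": self.area_lognormal,
            "base": sorted((t.value, k.value, v) for (t, k), v in self.density_base.items()),
            "offsets": sorted(self.zone_offsets.items()),
            "pop_offsets": sorted(self.zone_pop_offsets.items()),
            "area_offsets": sorted(self.zone_area_offsets.items()),
            "within_sigma": self.within_sigma,
            "trend": sorted((t.value, k.value, v) for (t, k), v in self.trend.items()),
            "inequality_drift": self.inequality_drift,
            "round": self.round_counts,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]


def generate_panel(config: GeneratorConfig | None = None) -> ResourcePanel:
    """Draw a balanced synthetic panel; bit-identical for equal configs."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    zone_of: list[str] = []
    region_ids: list[str] = []
    for zone in cfg.n_provinces_per_zone:  # insertion order
        for i in range(cfg.n_provinces_per_zone[zone]):
            region_ids.append(f"{zone[:1].upper()}{i + 1:02d}")
            zone_of.append(zone)
    nreg = len(region_ids)

    mu_p, sd_p = cfg.pop_lognormal
    mu_a, sd_a = cfg.area_lognormal
    pop_shift = np.array([cfg.zone_pop_offsets.get(z, 0.0) for z in zone_of])
    area_shift = np.array([cfg.zone_area_offsets.get(z, 0.0) for z in zone_of])
    pops = np.exp(rng.normal(mu_p, sd_p, size=nreg) + pop_shift)
    areas = np.exp(rng.normal(mu_a, sd_a, size=nreg) + area_shift)

    t0, t1 = cfg.years
    years = list(range(t0, t1 + 1))
    offsets = np.array([cfg.zone_offsets.get(z, 0.0) for z in zone_of])

    rows = []
    for t in years:
        dt = t - t0
        sigma_t = cfg.within_sigma + cfg.inequality_drift * dt
        if sigma_t < 0:
            raise ConfigError("inequality_drift drives the noise s.d. negative")
        counts = {}
        for tier, kind in VALID_COMBOS:
            base = cfg.density_base[(tier, kind)]
            drift = cfg.trend.get((tier, kind), 0.0)
            eta = rng.normal(0.0, sigma_t, size=nreg)
            dens = base * np.exp(offsets + eta + drift * dt)
            vals = dens * pops
            if cfg.round_counts:
                vals = np.round(vals)
                vals = np.where((dens > 0) & (vals < 1), 1.0, vals)
            counts[resource_column(tier, kind)] = vals
        for i in range(nreg):
            row = {
                "region_id": region_ids[i],
                "zone": zone_of[i],
                "year": t,
                "population": pops[i],
                "area_km2": areas[i],
            }
            for col, vals in counts.items():
                row[col] = vals[i]
            rows.append(row)

    return ResourcePanel(
        pd.DataFrame(rows), metadata={"config_hash": cfg.hash(), "seed": cfg.seed}
    )


def generate_two_block(
    pop_shares: tuple[float, float],
    resource_shares: tuple[float, float],
    calibre: Calibre = Calibre.POPULATION,
) -> AllocationVector:
    """Two-region allocation with closed-form G = |s - p| and
    T = p ln(p/s) + (1-p) ln((1-p)/(1-s)) (for 0 < s < 1)."""
    p, p2 = pop_shares
    s, s2 = resource_shares
    if not (0 < p < 1) or abs(p + p2 - 1) > 1e-12:
        raise EquipanelError("pop_shares must be (p, 1-p) with 0 < p < 1")
    if not (0 <= s <= 1) or abs(s + s2 - 1) > 1e-12:
        raise EquipanelError("resource_shares must be (s, 1-s) with 0 <= s <= 1")
    return AllocationVector(
        region_ids=("R1", "R2"),
        zones=("zone1", "zone2"),
        m=np.array([p, p2]),
        e=np.array([s, s2]),
        calibre=calibre,
    )


def inject_trend(
    panel: ResourcePanel,
    target_index: str,
    direction: int,
    strength: float | None = None,
    seed: int = 0,
) -> ResourcePanel:
    """Superimpose a monotone drift on a panel so a named index trends.

    target_index "gini" or "theil": the spread of log resource densities is
    widened (direction +1) or narrowed (direction -1) linearly over the
    window by multiplying counts with exp(lam_t * xi_i), xi_i ~ N(0, 1)
    fixed per region, lam_t ramping 0 -> strength.  The default strength
    0.52 (= 0.3 * sqrt(3)) doubles the generator's default log-density
    spread (within_sigma 0.3) by the final year — inequity growth of the
    magnitude the study period exhibits.

    target_index "hrdi": a uniform level drift exp(direction * strength * dt)
    (default strength 0.03/yr, a typical annual resource growth rate).

    direction 0 is the identity.
    """
    if target_index not in ("gini", "theil", "hrdi"):
        raise EquipanelError(f"unknown target index {target_index!r}")
    if direction not in (-1, 0, 1):
        raise EquipanelError("direction must be -1, 0 or +1")
    if direction == 0:
        return ResourcePanel(panel.frame, metadata=dict(panel.metadata))

    df = panel.frame
    years = sorted(df["year"].unique())
    t0, t1 = years[0], years[-1]
    span = max(t1 - t0, 1)
    regions = sorted(df["region_id"].unique())
    rng = np.random.default_rng(seed)
    rescols = [c for c in df.columns if c not in
               ("region_id", "zone", "year", "population", "area_km2")]

    if target_index in ("gini", "theil"):
        lam_max = 0.52 if strength is None else strength
        xi = dict(zip(regions, rng.normal(0.0, 1.0, size=len(regions))))
        ramp = {
            t: (lam_max * (t - t0) / span if direction > 0
                else lam_max * (t1 - t) / span)
            for t in years
        }
        factor = np.exp(
            df["year"].map(ramp).to_numpy() * df["region_id"].map(xi).to_numpy()
        )
    else:  # hrdi: level drift, sign as requested
        rho = 0.03 if strength is None else strength
        factor = np.exp(direction * rho * (df["year"].to_numpy() - t0))

    for c in rescols:
        df[c] = df[c].to_numpy() * factor

    meta = dict(panel.metadata)
    meta["injected_trend"] = {"index": target_index, "direction": direction}
    return ResourcePanel(df, metadata=meta)
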