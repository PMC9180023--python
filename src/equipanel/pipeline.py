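"""End-to-end analysis of a resource panel.

``run_analysis`` computes, for each of the 8 (tier, kind) combinations:
national resource totals with total and average growth rates; Gini series
under both calibres with fairness bands; zone + national HRDI series; the
yearly Theil decomposition (population calibre by default); the
within-zone contribution-rate table; and Mann-Kendall trend tests on every
emitted index series.  The result is a :class:`ReportBundle` of plain
DataFrames that ``write_bundle`` serialises as CSVs plus a JSON manifest.

The analysis is a pure function of (panel, options): re-running on the same
inputs reproduces every table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import EquipanelError, GrowthRateError
from .gini import gini_series
from .hrdi import DEFAULT_AREA_UNIT, DEFAULT_POP_UNIT, hrdi_series, hrdi_table
from .panel import Calibre, ResourcePanel, VALID_COMBOS, resource_column
from .theil import combo_label, contribution_table, theil_series
from .trend import mk_test


def total_growth(series) -> float:
    """Total growth over the window: (v_T - v_0) / v_0."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise GrowthRateError("need at least two values")
    if x[0] == 0:
        raise GrowthRateError("total growth undefined for a zero base value")
    return float((x[-1] - x[0]) / x[0])


def average_growth(series, mean: str = "geometric") -> float:
    """Average annual growth rate.

    "geometric" (default) is the compound rate (v_T/v_0)^(1/(T-t0)) - 1;
    "arithmetic" is the plain mean of the yearly growth rates.  Both are
    common readings of an "average growth rate" — the choice matters once
    growth is uneven.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise GrowthRateError("need at least two values")
    if np.any(x <= 0):
        raise GrowthRateError("growth rates need strictly positive values")
    if mean == "geometric":
        return float((x[-1] / x[0]) ** (1.0 / (x.size - 1)) - 1.0)
    if mean == "arithmetic":
        return float(np.mean(x[1:] / x[:-1] - 1.0))
    raise EquipanelError(f"unknown mean type {mean!r}")


@dataclass
class ReportBundle:
    """All tables the analysis emits, keyed the way they are written out."""

    status_quo: pd.DataFrame
    gini_series: pd.DataFrame
    hrdi_series: pd.DataFrame
    hrdi_cross_section: pd.DataFrame
    theil_series: pd.DataFrame
    contribution_table: pd.DataFrame
    trend_gini: pd.DataFrame
    trend_theil: pd.DataFrame
    trend_hrdi: pd.DataFrame
    run_metadata: dict = field(default_factory=dict)


def _mk_row(series: np.ndarray, **ids) -> dict:
    r = mk_test(series)
    return {
        **ids,
        "S": r.S,
        "var_s": r.var_s,
        "Z": r.Z,
        "z_3dp": round(r.Z, 3),
        "p_two_sided": r.p_two_sided,
        "stars": r.stars,
        "sign": r.sign_label,
        "cell": r.cell,
    }


def run_analysis(
    panel: ResourcePanel,
    calibres: tuple[Calibre, ...] = (Calibre.POPULATION, Calibre.GEOGRAPHY),
    theil_calibre: Calibre = Calibre.POPULATION,
    cross_section_year: int | None = None,
    growth_mean: str = "geometric",
    pop_unit: float = DEFAULT_POP_UNIT,
    area_unit: float = DEFAULT_AREA_UNIT,
    keep_going: bool = False,
) -> ReportBundle:
    """Run the full equity analysis; see module docstring.

    With ``keep_going`` a failing stage is recorded in run_metadata["errors"]
    and the remaining stages still run; otherwise the first error aborts the
    run with (stage, tier, kind, calibre) context attached.
    """
    errors: list[str] = []

    def guard(stage: str, fn, **ids):
        try:
            return fn()
        except EquipanelError as exc:
            ctx = ", ".join(f"{k}={v}" for k, v in ids.items())
            msg = f"{stage} [{ctx}]: {exc}"
            if keep_going:
                errors.append(msg)
                return None
            raise EquipanelError(msg) from exc

    years = panel.years
    csy = cross_section_year if cross_section_year is not None else years[-1]

    # --- status quo: national totals and growth rates --------------------
    df = panel.frame
    totals = df.groupby("year")[[resource_column(t, k) for t, k in VALID_COMBOS]].sum()
    sq_rows = []
    for tier, kind in VALID_COMBOS:
        col = resource_column(tier, kind)
        series = totals[col].to_numpy()
        sq_rows.append(
            {
                "tier": tier.value,
                "kind": kind.value,
                "first_year_total": series[0],
                "last_year_total": series[-1],
                "total_growth_pct": round(100 * total_growth(series), 2),
                "average_growth_pct": round(
                    100 * average_growth(series, mean=growth_mean), 2
                ),
            }
        )
    status_quo = pd.DataFrame(sq_rows)

    # --- Gini series ------------------------------------------------------
    g_rows = []
    for tier, kind in VALID_COMBOS:
        for calibre in calibres:
            res = guard(
                "gini",
                lambda: gini_series(panel, tier, kind, calibre),
                tier=tier.value, kind=kind.value, calibre=calibre.value,
            )
            if res is None:
                continue
            for r in res:
                g_rows.append(
                    {
                        "year": r.year,
                        "tier": tier.value,
                        "kind": kind.value,
                        "calibre": calibre.value,
                        "gini": r.G,
                        "band": r.band,
                    }
                )
    gini_df = pd.DataFrame(g_rows)

    # --- HRDI -------------------------------------------------------------
    hrdi_df = hrdi_series(panel, pop_unit, area_unit)
    cross = pd.DataFrame(
        [
            {
                "scope": r.scope,
                "level": r.level,
                "tier": r.tier.value,
                "kind": r.kind.value,
                "year": r.year,
                "hrdi": r.hrdi,
            }
            for r in hrdi_table(panel, csy, "province", pop_unit, area_unit)
        ]
    )

    # --- Theil ------------------------------------------------------------
    t_rows = []
    for tier, kind in VALID_COMBOS:
        res = guard(
            "theil",
            lambda: theil_series(panel, tier, kind, theil_calibre),
            tier=tier.value, kind=kind.value, calibre=theil_calibre.value,
        )
        if res is None:
            continue
        for d in res:
            row = {
                "year": d.year,
                "tier": tier.value,
                "kind": kind.value,
                "calibre": theil_calibre.value,
                "t_total": d.T_total,
                "t_inter": d.T_inter,
                "t_intra": d.T_intra,
                "contrib_intra_pct": round(100 * d.contrib_intra, 2),
                "contrib_inter_pct": round(100 * d.contrib_inter, 2),
            }
            for zone, (tg, wg) in d.per_zone.items():
                row[f"t_within_{zone}"] = tg
            t_rows.append(row)
    theil_df = pd.DataFrame(t_rows)

    contrib = guard(
        "contribution_table",
        lambda: contribution_table(panel, theil_calibre),
        calibre=theil_calibre.value,
    )
    if contrib is None:
        contrib = pd.DataFrame()

    # --- Mann-Kendall trend tables ----------------------------------------
    tg_rows = []
    if len(gini_df):
        for (tier, kind, calibre), sub in gini_df.groupby(
            ["tier", "kind", "calibre"], sort=True
        ):
            s = sub.sort_values("year")["gini"].to_numpy()
            tg_rows.append(_mk_row(s, tier=tier, kind=kind, calibre=calibre))
    trend_gini = pd.DataFrame(tg_rows)

    tt_rows = []
    if len(theil_df):
        for (tier, kind), sub in theil_df.groupby(["tier", "kind"], sort=True):
            sub = sub.sort_values("year")
            for component, col in (
                ("total", "t_total"), ("inter", "t_inter"), ("intra", "t_intra"),
            ):
                tt_rows.append(
                    _mk_row(
                        sub[col].to_numpy(),
                        tier=tier, kind=kind, component=component,
                    )
                )
    trend_theil = pd.DataFrame(tt_rows)

    th_rows = []
    for (scope, tier, kind), sub in hrdi_df.groupby(
        ["scope", "tier", "kind"], sort=True
    ):
        s = sub.sort_values("year")["hrdi"].to_numpy()
        th_rows.append(_mk_row(s, scope=scope, tier=tier, kind=kind))
    trend_hrdi = pd.DataFrame(th_rows)

    meta = {
        "version": __version__,
        "panel_metadata": dict(panel.metadata),
        "years": [years[0], years[-1]],
        "n_regions": len(panel.regions),
        "calibres": [c.value for c in calibres],
        "theil_calibre": theil_calibre.value,
        "cross_section_year": csy,
        "growth_mean": growth_mean,
        "pop_unit": pop_unit,
        "area_unit": area_unit,
    }
    if errors:
        meta["errors"] = errors

    return ReportBundle(
        status_quo=status_quo,
        gini_series=gini_df,
        hrdi_series=hrdi_df,
        hrdi_cross_section=cross,
        theil_series=theil_df,
        contribution_table=contrib,
        trend_gini=trend_gini,
        trend_theil=trend_theil,
        trend_hrdi=trend_hrdi,
        run_metadata=meta,
    )


_ARTIFACTS = (
    ("status_quo", "status_quo.csv"),
    ("gini_series", "gini_series.csv"),
    ("hrdi_series", "hrdi_series.csv"),
    ("hrdi_cross_section", "hrdi_cross_section.csv"),
    ("theil_series", "theil_series.csv"),
    ("contribution_table", "contribution_table.csv"),
    ("trend_gini", "trend_gini.csv"),
    ("trend_theil", "trend_theil.csv"),
    ("trend_hrdi", "trend_hrdi.csv"),
)


def write_bundle(bundle: ReportBundle, out_dir) -> dict:
    """Write every table as CSV plus ``manifest.json``; returns the manifest.

    Floats are written with repr-round-trip precision and fixed column
    order, so identical bundles produce identical bytes and hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for attr, name in _ARTIFACTS:
        df: pd.DataFrame = getattr(bundle, attr)
        path = out / name
        index = attr == "contribution_table"
        df.to_csv(path, index=index)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        files.append({"name": name, "sha256": digest, "rows": int(len(df))})
    manifest = {
        "version": bundle.run_metadata.get("version"),
        "config_hash": bundle.run_metadata.get("panel_metadata", {}).get("config_hash"),
        "run_metadata": bundle.run_metadata,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
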