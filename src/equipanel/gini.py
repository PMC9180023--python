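"""Lorenz curves and the trapezoid Gini coefficient on grouped regional data.

Regions are sorted ascending by resource density e_i/m_i (the standard
Lorenz ordering, guaranteeing G >= 0), cumulative measure shares X_i and
resource shares Y_i are formed with the implicit origin (X_0, Y_0) = (0, 0),
and the Gini coefficient is the trapezoid sum

    G = 1 - sum_i (X_i - X_{i-1}) (Y_i + Y_{i-1}).

On grouped data this is algebraically identical to the weighted relative
mean difference  sum_ij w_i w_j |d_i - d_j| / (2 dbar)  with w_i = m_i/M,
d_i = e_i/m_i, dbar = sum_i w_i d_i — the oracle used in the test suite.

Fairness bands follow the conventional thresholds: G below 0.3 is optimal,
0.3-0.4 normal, 0.4-0.5 a visible gap, 0.5-0.6 alert, 0.6 and above danger.
Bands are half-open [a, b) so every G maps to exactly one band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateAllocationError, EquipanelError
from .panel import AllocationVector, Calibre, ResourceKind, ResourcePanel, Tier

#: Band lower edges, ascending, with labels.
_BANDS = (
    (0.0, "optimal"),
    (0.3, "normal"),
    (0.4, "gap"),
    (0.5, "alert"),
    (0.6, "danger"),
)


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative-share points (X_i, Y_i), starting at (0, 0), ending at (1, 1)."""

    X: np.ndarray
    Y: np.ndarray

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.X.tolist(), self.Y.tolist()))


@dataclass(frozen=True)
class GiniResult:
    G: float
    band: str
    calibre: Calibre
    tier: Tier | None = None
    kind: ResourceKind | None = None
    year: int | None = None


def _sorted_shares(alloc: AllocationVector) -> tuple[np.ndarray, np.ndarray]:
    """Measure and resource shares sorted ascending by density e/m.

    Ties in density are broken by region_id so the construction is fully
    deterministic.
    """
    if alloc.e.sum() <= 0:
        raise DegenerateAllocationError(
            "all resource quantities are zero; Lorenz curve undefined"
        )
    density = alloc.e / alloc.m
    order = np.lexsort((np.asarray(alloc.region_ids), density))
    w = alloc.measure_shares[order]
    s = alloc.resource_shares[order]
    return w, s


def lorenz_curve(alloc: AllocationVector) -> LorenzCurve:
    """Lorenz curve of a cross-section: resource share vs measure share."""
    w, s = _sorted_shares(alloc)
    X = np.concatenate([[0.0], np.cumsum(w)])
    Y = np.concatenate([[0.0], np.cumsum(s)])
    # guard against accumulated round-off at the endpoint
    X[-1] = 1.0
    Y[-1] = 1.0
    return LorenzCurve(X=X, Y=Y)


def gini(alloc: AllocationVector) -> GiniResult:
    """Trapezoid Gini coefficient of a cross-section, with fairness band."""
    curve = lorenz_curve(alloc)
    X, Y = curve.X, curve.Y
    G = 1.0 - float(np.sum(np.diff(X) * (Y[1:] + Y[:-1])))
    G = max(G, 0.0)  # clip -eps round-off on proportional allocations
    return GiniResult(
        G=G,
        band=classify_gini(G),
        calibre=alloc.calibre,
        tier=alloc.tier,
        kind=alloc.kind,
        year=alloc.year,
    )


def classify_gini(G: float) -> str:
    """Fairness band for a Gini value; bands are left-closed, right-open."""
    if not 0 <= G < 1:
        raise EquipanelError(f"Gini value {G} outside [0, 1)")
    label = _BANDS[0][1]
    for lo, name in _BANDS:
        if G >= lo:
            label = name
    return label


def gini_series(
    panel: ResourcePanel, tier: Tier, kind: ResourceKind, calibre: Calibre
) -> list[GiniResult]:
    """One GiniResult per panel year, ascending year order."""
    return [
        gini(panel.slice_allocation(year, tier, kind, calibre))
        for year in panel.years
    ]
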