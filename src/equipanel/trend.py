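"""Mann-Kendall nonparametric trend test.

The statistic counts concordant minus discordant pairs,

    S = sum_{i<j} sgn(x_j - x_i),

so a rising series gives S > 0.  Under the null of no trend (exchangeable
observations) S has mean 0 and tie-corrected variance

    Var(S) = [ n(n-1)(2n+5) - sum_t f_t (f_t - 1)(2 f_t + 5) ] / 18,

where f_t is the size of the t-th tie group.  The normal score applies a
continuity correction:

    Z = (S - 1)/sqrt(Var)  if S > 0,   0 if S = 0,   (S + 1)/sqrt(Var)  if S < 0,

and is referred to the standard normal.  Significance is flagged on the
three-level ladder *** p<0.01, ** p<0.05, * p<0.1 (two-sided by default).

S is a rank statistic: any strictly increasing transform of the series
leaves S, Var and Z unchanged.  For an 18-point strictly monotone series the
ceiling value is Z = 152/sqrt(697) ~ 5.757.

``exact_null`` provides the exact permutation distribution of S for small n
(distinct values) as an independent check on the normal approximation; it is
computed with the inversion-count recurrence rather than by enumerating n!
orderings, which gives the identical distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError, EquipanelError, SeriesTooShortError

#: Significance ladder: (alpha, stars), descending stringency.
ALPHA_LADDER = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


@dataclass(frozen=True)
class MKResult:
    S: int
    var_s: float
    Z: float
    p_two_sided: float
    direction: str  # "increasing" | "decreasing" | "none"
    stars: str

    @property
    def sign_label(self) -> str:
        return {"increasing": "(+)", "decreasing": "(−)", "none": "(0)"}[
            self.direction
        ]

    @property
    def cell(self) -> str:
        """Table-cell formatting, e.g. ``5.757 *** (+)``."""
        z = f"{self.Z:.3f}".replace("-", "−")
        stars = f" {self.stars}" if self.stars else ""
        return f"{z}{stars} {self.sign_label}"


def _as_series(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise EquipanelError("series must be one-dimensional")
    if x.size < 2:
        raise SeriesTooShortError("Mann-Kendall needs at least 2 observations")
    return x


def mk_s(series) -> int:
    """Concordance statistic S = sum_{i<j} sgn(x_j - x_i); sgn(0) = 0."""
    x = _as_series(series)
    diff = np.sign(x[None, :] - x[:, None])
    return int(np.triu(diff, k=1).sum())


def mk_variance(series) -> float:
    """Tie-corrected null variance of S."""
    x = _as_series(series)
    n = x.size
    _, counts = np.unique(x, return_counts=True)
    tie_term = np.sum(counts * (counts - 1) * (2 * counts + 5))
    return float(n * (n - 1) * (2 * n + 5) - tie_term) / 18.0


def mk_test(series, alphas=ALPHA_LADDER, one_sided: bool = False) -> MKResult:
    """Full Mann-Kendall test with continuity correction and star flags.

    ``alphas`` may be a sequence of (alpha, stars) pairs (most stringent
    first) or of bare alpha levels, in which case the default star strings
    are attached in order.
    """
    x = _as_series(series)
    S = mk_s(x)
    var = mk_variance(x)

    if S == 0:
        Z = 0.0
    else:
        if var <= 0:
            raise DegenerateVarianceError(
                "zero Mann-Kendall variance with non-zero S"
            )
        Z = (S - 1) / math.sqrt(var) if S > 0 else (S + 1) / math.sqrt(var)

    p = float(2.0 * stats.norm.sf(abs(Z)))
    p = min(p, 1.0)
    p_used = p / 2.0 if one_sided else p

    ladder = []
    for item in alphas:
        if isinstance(item, (tuple, list)):
            ladder.append((float(item[0]), str(item[1])))
        else:
            ladder.append((float(item), ""))
    ladder.sort(key=lambda t: t[0])
    if any(not s for _, s in ladder):
        defaults = ["***", "**", "*"]
        ladder = [(a, defaults[i] if i < 3 else "*") for i, (a, _) in enumerate(ladder)]

    stars = ""
    for alpha, star in ladder:
        if p_used < alpha:
            stars = star
            break

    direction = "increasing" if Z > 0 else ("decreasing" if Z < 0 else "none")
    return MKResult(
        S=S, var_s=var, Z=float(Z), p_two_sided=p, direction=direction, stars=stars
    )


def exact_null(n: int) -> dict[int, float]:
    """Exact permutation distribution of S for n distinct values.

    Returns {s: P(S = s)} over all n! equally likely orderings.  Uses the
    inversion-number recurrence: a permutation with k inversions has
    S = n(n-1)/2 - 2k, and the inversion counts satisfy
    I_n(k) = sum_{j=0}^{n-1} I_{n-1}(k - j).
    """
    if not 2 <= n <= 10:
        raise EquipanelError("exact null supported for 2 <= n <= 10")
    # counts[k] = number of permutations of {1..m} with k inversions
    counts = np.array([1], dtype=float)
    for m in range(2, n + 1):
        kernel = np.ones(m)
        counts = np.convolve(counts, kernel)
    counts /= math.factorial(n)
    smax = n * (n - 1) // 2
    return {smax - 2 * k: float(p) for k, p in enumerate(counts)}


def trend_table(series_bundle: dict[str, "np.ndarray"], **mk_kwargs):
    """Mann-Kendall results for a bundle of named series.

    Returns a DataFrame with one row per series: S, var_s, Z (full
    precision), z_3dp, p, stars, sign and the formatted ``cell`` string.
    """
    import pandas as pd

    rows = []
    for name, series in series_bundle.items():
        r = mk_test(series, **mk_kwargs)
        rows.append(
            {
                "series": name,
                "S": r.S,
                "var_s": r.var_s,
                "Z": r.Z,
                "z_3dp": round(r.Z, 3),
                "p_two_sided": r.p_two_sided,
                "stars": r.stars,
                "sign": r.sign_label,
                "cell": r.cell,
            }
        )
    return pd.DataFrame(rows)
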