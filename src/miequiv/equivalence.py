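"""Equivalence testing for chi-square statistics.

Converts an observed chi-square (or chi-square-difference) statistic into
the minimum tolerable size of misspecification ("T-size"): the
noncentrality delta_t at which the observed statistic equals the
alpha-level left-tail critical value of the noncentral chi-square
distribution.  On the discrepancy scale epsilon_t = delta_t / (N - m),
and RMSEA_t = sqrt(m * epsilon_t / df).  RMSEA_t is judged against
sample-size- and df-adjusted cutoffs aligned with the conventional
0.01 / 0.05 / 0.08 / 0.10 anchors, yielding one of the labels
excellent / close / fair / mediocre / poor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import chi2, ncx2

__all__ = [
    "EquivalenceResult",
    "invert_ncp",
    "tsize",
    "adjusted_cutoffs",
    "fit_label",
    "LABELS",
]

LABELS = ("excellent", "close", "fair", "mediocre", "poor")


@dataclass(frozen=True)
class EquivalenceResult:
    """T-size noncentrality, misspecification, RMSEA, adjusted cutoffs and
    goodness-of-fit label for one statistic."""

    statistic: float
    df: int
    n_total: int
    n_groups: int
    alpha: float
    delta_t: float
    epsilon_t: float
    rmsea_t: float
    cutoffs: tuple[float, float, float, float]
    label: str


def invert_ncp(t: float, df: int, alpha: float = 0.05,
               tol: float = 1e-10) -> float:
    """Noncentrality delta such that the alpha-quantile of
    ``ncx2(df, delta)`` equals ``t``; 0 when ``t`` is at or below the
    central alpha-quantile.  Monotone bisection."""
    if t < 0:
        raise ValueError("statistic must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if t <= chi2.ppf(alpha, df):
        return 0.0
    lo, hi = 0.0, t + 10.0 * math.sqrt(t) + 100.0
    # quantile_alpha(df, delta) is increasing in delta
    while ncx2.ppf(alpha, df, hi) < t:
        lo, hi = hi, hi * 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        q = ncx2.ppf(alpha, df, mid) if mid > 0 else chi2.ppf(alpha, df)
        if q < t:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def tsize(t: float, df: int, n_total: int, m: int, alpha: float = 0.05,
          stat_family: str = "likelihood_ratio",
          divisor: str | None = None) -> EquivalenceResult:
    """T-size misspecification and RMSEA for an observed statistic.

    ``stat_family`` is ``"likelihood_ratio"`` for chi-square and
    chi-square-difference statistics or ``"wald_projection"`` for the
    projection-method Wald statistics.  The delta <-> epsilon divisor is
    N - m for both families by default (``divisor="n"`` selects N, the
    variant stated for the projection Wald family).
    """
    if stat_family not in ("likelihood_ratio", "wald_projection"):
        raise ValueError(f"unknown stat_family {stat_family!r}")
    if df < 1:
        raise ValueError("T-size is undefined at df = 0")
    if n_total <= m:
        raise ValueError("n_total must exceed the number of groups")
    if divisor is None:
        divisor = "n_minus_m"
    if divisor == "n_minus_m":
        div = n_total - m
    elif divisor == "n":
        div = n_total
    else:
        raise ValueError(f"unknown divisor {divisor!r}")
    delta = invert_ncp(t, df, alpha)
    eps = delta / div
    rmsea = math.sqrt(m * eps / df)
    cuts = adjusted_cutoffs(df, n_total, m)
    return EquivalenceResult(
        statistic=float(t), df=int(df), n_total=int(n_total), n_groups=int(m),
        alpha=float(alpha), delta_t=float(delta), epsilon_t=float(eps),
        rmsea_t=float(rmsea), cutoffs=cuts, label=fit_label(rmsea, cuts),
    )


# Log-linear cutoff surfaces in (df, n) with n the per-group effective
# sample size N/m - 1.  Terms: 1, ln df, (ln df)^2, ln n, g(n), ln df * ln n
# with g(n) = sqrt(n) for the .01 anchor, n for .05 and n^0.2 for .08/.10.
_CUTOFF_COEF = {
    "cut.01": (1.34863, -0.51999, 0.01925, -0.59811, 0.00902, 0.01796),
    "cut.05": (2.06058, -0.62786, 0.02512, -0.98388, -0.00005188, 0.05260),
    "cut.08": (2.85094, -0.55278, 0.02296, -0.76005, -1.11167, 0.04845),
    "cut.10": (2.37809, -0.50134, 0.02131, -0.64445, -1.01634, 0.04422),
}
_CUTOFF_EXTRA = {
    "cut.01": lambda n: math.sqrt(n),
    "cut.05": lambda n: n,
    "cut.08": lambda n: n ** 0.2,
    "cut.10": lambda n: n ** 0.2,
}
_CUTOFF_LNN2 = {"cut.01": 0.0, "cut.05": 0.05442, "cut.08": 0.10229,
                "cut.10": 0.09043}


def adjusted_cutoffs(df: int, n_total: int, m: int = 1
                     ) -> tuple[float, float, float, float]:
    """Adjusted RMSEA cutoffs aligned with the 0.01/0.05/0.08/0.10 anchors.

    Uses the per-group effective sample size n = N/m - 1.  The fitted
    surfaces are calibrated for moderate df and n; outside df in [1, 100]
    or n in [30, 10000] a warning is attached.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    n = n_total / m - 1.0
    if n <= 1:
        raise ValueError("per-group sample size too small for cutoffs")
    if not (1 <= df <= 100) or not (30 <= n <= 10000):
        warnings.warn(
            f"adjusted cutoffs extrapolated outside fitted range "
            f"(df={df}, per-group n={n:.0f})",
            RuntimeWarning, stacklevel=2,
        )
    ldf, lnn = math.log(df), math.log(n)
    out = []
    for key, (a, b, c, d, e, f) in _CUTOFF_COEF.items():
        val = math.exp(
            a + b * ldf + c * ldf * ldf + d * lnn
            + _CUTOFF_LNN2[key] * lnn * lnn
            + e * _CUTOFF_EXTRA[key](n) + f * ldf * lnn
        )
        out.append(val)
    c01, c05, c08, c10 = out
    if not (c01 < c05 < c08 < c10):
        warnings.warn(
            "adjusted cutoffs not strictly increasing; outside the fitted "
            "range of the cutoff surfaces",
            RuntimeWarning, stacklevel=2,
        )
    return (c01, c05, c08, c10)


def fit_label(rmsea_t: float, cutoffs) -> str:
    """Label RMSEA_t against four increasing cutoff values."""
    c01, c05, c08, c10 = cutoffs
    if not (c01 < c05 < c08 < c10):
        raise ValueError("cutoffs must be strictly increasing")
    if rmsea_t < c01:
        return "excellent"
    if rmsea_t < c05:
        return "close"
    if rmsea_t < c08:
        return "fair"
    if rmsea_t < c10:
        return "mediocre"
    return "poor"
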