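"""Goodness-of-fit statistics and the paired Wilcoxon signed-rank test.

RMSE uses the degrees-of-freedom-corrected denominator n - s, where s is
the number of fitted parameters (s = 0 gives the plain root mean square,
used for the ML regressors where a parameter count is undefined).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError

__all__ = ["rmse", "r_squared", "sse_sst", "wilcoxon_signed_rank"]

#: largest sample size for which the exact signed-rank distribution is used
EXACT_WILCOXON_N = 25


def sse_sst(observed, fitted) -> Tuple[float, float]:
    """Sum of squared errors and total sum of squares about the observed mean."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    sse = float(np.sum((observed - fitted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    return sse, sst


def rmse(observed, fitted, s: int = 0) -> float:
    """Root mean square error with n - s degrees of freedom."""
    observed = np.asarray(observed, dtype=float)
    n = observed.size
    if n <= s:
        raise DomainError(f"need more observations ({n}) than parameters ({s})")
    err, _ = sse_sst(observed, fitted)
    return float(np.sqrt(err / (n - s)))


def r_squared(observed, fitted) -> float:
    """Coefficient of determination R^2 = 1 - SSE/SST."""
    err, tot = sse_sst(observed, fitted)
    if tot == 0:
        raise DegenerateDataError("R^2 undefined: observed values are constant")
    return 1.0 - err / tot


def _signed_rank_statistic(diffs: np.ndarray) -> Tuple[float, float, np.ndarray]:
    """Return (W+, W-, ranks) using mid-ranks for tied |differences|."""
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    return w_plus, w_minus, ranks


def _exact_sf_cdf(ranks: np.ndarray, w: float) -> Tuple[float, float]:
    """Exact P(W+ <= w) and total mass, by DP over the rank-sum distribution.

    Mid-ranks are multiples of 1/2, so doubling them gives integers and the
    distribution of 2*W+ over the 2^n equiprobable sign assignments can be
    built by convolution.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()
    w2 = int(np.rint(2.0 * w))
    cdf = counts[: w2 + 1].sum() / counts.sum()
    return cdf, counts.sum()


def wilcoxon_signed_rank(paired_a, paired_b=None) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Accepts either two paired samples or a single vector of differences.
    Zero differences are dropped before ranking (Wilcoxon's original
    procedure) and tied absolute differences share mid-ranks.  For up to
    25 non-zero pairs the p-value is exact (P(min(W+, W-) <= observed)
    computed from the full sign-assignment distribution, equal to
    2 * P(W+ <= min(W+, W-)) by symmetry, capped at 1); beyond that a
    normal approximation with tie correction is used.

    Returns (statistic, p_value) where the statistic is min(W+, W-).
    """
    a = np.asarray(paired_a, dtype=float)
    if paired_b is not None:
        b = np.asarray(paired_b, dtype=float)
        if a.shape != b.shape:
            raise DomainError("paired samples must have equal length")
        diffs = a - b
    else:
        diffs = a
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")

    w_plus, w_minus, ranks = _signed_rank_statistic(diffs)
    w = min(w_plus, w_minus)

    if n <= EXACT_WILCOXON_N:
        cdf, _ = _exact_sf_cdf(ranks, w)
        p = min(1.0, 2.0 * cdf)
    else:
        mu = n * (n + 1) / 4.0
        # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
    return float(w), float(p)
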