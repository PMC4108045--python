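"""Wilcoxon signed-rank test for paired differences.

Exact zeros are discarded before ranking. For n <= 25 non-zero differences
the null distribution of the positive-rank sum is enumerated exactly (by
dynamic programming over the 2^n sign assignments, which handles midranks
from ties); beyond that a normal approximation with tie correction and a
continuity correction is used. An all-zero input returns p = 1.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

EXACT_LIMIT = 25


def _exact_p(ranks: np.ndarray, w_plus: float, alternative: str) -> float:
    # double midranks so every rank is an integer; DP over achievable sums
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    t = int(np.rint(2.0 * w_plus))
    p_ge = counts[t:].sum()
    p_le = counts[: t + 1].sum()
    if alternative == "greater":
        return float(min(p_ge, 1.0))
    if alternative == "less":
        return float(min(p_le, 1.0))
    # distribution is symmetric about total/2 under the null
    return float(min(2.0 * min(p_ge, p_le), 1.0))


def _approx_p(d: np.ndarray, ranks: np.ndarray, w_plus: float, alternative: str) -> float:
    from scipy.stats import norm

    n = d.size
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, t_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(t_counts**3 - t_counts) / 48.0
    sd = np.sqrt(var)
    if sd == 0:
        return 1.0
    if alternative == "greater":
        return float(norm.sf((w_plus - 0.5 - mu) / sd))
    if alternative == "less":
        return float(norm.cdf((w_plus + 0.5 - mu) / sd))
    z = (abs(w_plus - mu) - 0.5) / sd
    return float(min(2.0 * norm.sf(max(z, 0.0)), 1.0))


def wilcoxon_signed_rank(differences: np.ndarray, alternative: str = "two-sided") -> float:
    """p-value for the null that ``differences`` are symmetric about zero.

    ``alternative``: "two-sided", "greater" (center > 0) or "less".
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a non-empty 1-D vector")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= EXACT_LIMIT:
        return _exact_p(ranks, w_plus, alternative)
    return _approx_p(d, ranks, w_plus, alternative)
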