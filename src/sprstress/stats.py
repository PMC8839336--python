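"""Paired nonparametric comparison: Wilcoxon signed-rank test.

The exact null distribution is obtained by enumerating all 2^n sign
assignments of the rank values (via a subset-sum recursion over doubled
ranks, so mid-ranks — which are half-integers under ties — stay exact).
Zero differences are dropped; ties among |differences| get mid-ranks.
A normal approximation with tie and continuity corrections is used for
larger samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["PairedTestResult", "wilcoxon_signed_rank"]

EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float      # min(W+, W-)
    p_value: float
    n_pairs: int          # pairs remaining after dropping zero differences
    alternative: str
    method: str


def _exact_counts(double_ranks: np.ndarray) -> np.ndarray:
    """counts[s] = number of sign assignments with doubled positive-rank sum s."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted if r else counts * 2
    return counts


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
    method: str = "auto",
) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired samples ``x`` and ``y``.

    ``method`` is ``"exact"`` (full enumeration), ``"approx"`` (normal
    approximation), or ``"auto"`` (exact up to n = 25 non-zero pairs).
    ``alternative="greater"`` tests whether x - y tends to be positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = x - y
    d = d[d != 0]  # zero differences carry no sign information
    n = len(d)
    if n == 0:
        raise ValueError("degenerate input: all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero paired differences")

    ranks = rankdata(np.abs(d))  # mid-ranks under ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    if method == "auto":
        method = "exact" if n <= EXACT_MAX_N else "approx"

    if method == "exact":
        dbl = np.round(2 * ranks).astype(int)
        counts = _exact_counts(dbl)
        total = counts.sum()  # 2^n
        s = int(round(2 * w_plus))
        cdf = counts[: s + 1].sum() / total
        sf = counts[s:].sum() / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(cdf, sf))
        elif alternative == "greater":
            p = sf
        else:
            p = cdf
    elif method == "approx":
        mean = n * (n + 1) / 4.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_sizes**3 - tie_sizes).sum() / 48.0
        sd = np.sqrt(var)
        if alternative == "two-sided":
            z = (abs(w_plus - mean) - 0.5) / sd
            p = 2.0 * norm.sf(z)
        elif alternative == "greater":
            p = norm.sf((w_plus - mean - 0.5) / sd)
        else:
            p = norm.cdf((w_plus - mean + 0.5) / sd)
        p = min(1.0, float(p))
    else:
        raise ValueError(f"unknown method {method!r}")

    return PairedTestResult(statistic=min(w_plus, w_minus), p_value=float(p),
                            n_pairs=n, alternative=alternative, method=method)
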