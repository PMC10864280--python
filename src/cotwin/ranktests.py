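"""Wilcoxon signed-rank test with an exact tie-aware null distribution.

The paired screens test within-pair differences (affected minus healthy
co-twin). Zero differences are discarded before ranking (the classical
convention) and tied absolute differences receive mid-ranks. For small
numbers of pairs the p-value is exact: the null distribution of the
positive-rank sum is computed over all 2^n sign assignments of the
observed mid-ranks (by dynamic programming on the doubled ranks, which are
integers). For larger n a normal approximation with tie correction and
continuity correction is used.

The exact path is implemented here because the common library routine's
exact mode assumes untied ranks; mid-rank exactness is required for count
data, where ties are routine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SignedRankResult", "signed_rank_test", "exact_signed_rank_distribution"]

#: above this many nonzero differences, switch to the normal approximation
EXACT_LIMIT = 25


@dataclass
class SignedRankResult:
    statistic: float      # positive-rank sum W+
    p_value: float
    n_used: int           # nonzero differences entering the test
    method: str           # "exact" | "normal" | "degenerate"
    direction: int        # sign of the median within-pair difference


def exact_signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of W+ for the given (possibly tied) mid-ranks.

    Returns ``(support, pmf)`` where support is in units of the original
    ranks. Works on doubled ranks so mid-ranks (.5 steps) stay integral;
    the pmf enumerates all 2^n equally likely sign assignments.
    """
    doubled = np.round(2 * np.asarray(ranks, dtype=float)).astype(int)
    if np.any(np.abs(2 * ranks - doubled) > 1e-9):
        raise ValueError("ranks must be integers or half-integers")
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    pmf = counts / counts.sum()
    support = np.arange(total + 1) / 2.0
    return support, pmf


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def signed_rank_test(differences: np.ndarray,
                     exact_limit: int = EXACT_LIMIT) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    The two-sided p doubles the smaller tail probability of W+ (capped at
    1). With all differences zero the test is degenerate: p = 1 and
    direction 0.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be a 1-D vector")
    if np.isnan(d).any():
        raise ValueError("differences contain NaN")
    med = np.median(d)
    direction = int(np.sign(med))
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return SignedRankResult(np.nan, 1.0, 0, "degenerate", direction)

    ranks = _midranks(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())

    if n <= exact_limit:
        support, pmf = exact_signed_rank_distribution(ranks)
        lower = pmf[support <= w_plus + 1e-9].sum()
        upper = pmf[support >= w_plus - 1e-9].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(np.abs(nz), return_counts=True)
        var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
        if var <= 0:
            return SignedRankResult(w_plus, 1.0, n, "degenerate", direction)
        from scipy.stats import norm
        # continuity-corrected two-sided normal approximation
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "normal"
    return SignedRankResult(w_plus, float(p), n, method, direction)
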