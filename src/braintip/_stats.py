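"""Shared statistical kernels.

The two-group comparison used throughout (differential expression, the
sliding-window scan, noise comparisons) is the Wilcoxon rank-sum test in its
tie-corrected normal approximation, without continuity correction — the
convention of standard single-cell toolkits. At pseudobulk group sizes of
3–6 donors per side this approximation keeps the attained size close to the
nominal level, whereas the exact test's discrete support makes it strongly
conservative.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum test per column.

    Parameters
    ----------
    a, b
        Arrays of shape ``(n_a, n_features)`` and ``(n_b, n_features)``.

    Returns
    -------
    z, p
        Per-feature z statistic (positive when ``a`` ranks higher) and
        two-sided p-value.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("a and b must have the same number of features")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    n = n_a + n_b
    pooled = np.concatenate([a, b], axis=0)
    ranks = stats.rankdata(pooled, axis=0)
    rank_sum_a = ranks[:n_a].sum(axis=0)
    mu = n_a * (n + 1) / 2.0

    # tie correction: sum of (t^3 - t) over tied groups, per feature
    sorted_cols = np.sort(pooled, axis=0)
    tie_term = np.zeros(pooled.shape[1])
    boundaries = np.diff(sorted_cols, axis=0) != 0
    for j in range(pooled.shape[1]):
        # run lengths of equal values in column j
        idx = np.flatnonzero(boundaries[:, j])
        run_lengths = np.diff(np.concatenate(([0], idx + 1, [n])))
        t = run_lengths[run_lengths > 1]
        if t.size:
            tie_term[j] = np.sum(t**3 - t)
    sigma_sq = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    sigma = np.sqrt(sigma_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (rank_sum_a - mu) / sigma
    z = np.where(sigma == 0, 0.0, z)  # all values tied -> no evidence
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, np.minimum(p, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values; NaNs pass through untouched."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = stats.false_discovery_control(p[mask], method="bh")
    return q
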