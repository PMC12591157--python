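"""Two-group Wilcoxon differential expression and DEG-overlap statistics.

A gene is called *up* in group A when its BH-adjusted rank-sum p-value falls
below ``alpha`` and the (de-logged) fold change of A over B exceeds
``fc_threshold``; symmetrically for *down*. Genes expressed in fewer than
``min_pct`` of cells in both groups are excluded from testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from ._stats import bh_adjust, rank_sum_test

_EPS = 1e-9


def rank_sum_de(
    norm_expr: sparse.spmatrix | np.ndarray,
    labels: np.ndarray | pd.Series,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    *,
    min_pct: float = 0.1,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between label groups A and B.

    ``norm_expr`` is genes × cells (log-normalized); ``labels`` holds "A"/"B"
    per cell. Fold change is computed on de-logged group means,
    ``(mean(expm1 x_A) + eps) / (mean(expm1 x_B) + eps)``.
    """
    labels = np.asarray(labels)
    mask_a = labels == "A"
    mask_b = labels == "B"
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs at least 3 cells")
    x = norm_expr.toarray() if sparse.issparse(norm_expr) else np.asarray(norm_expr, float)
    n_genes = x.shape[0]
    a = x[:, mask_a]
    b = x[:, mask_b]

    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)

    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    fold = (mean_a + _EPS) / (mean_b + _EPS)
    log2_fc = np.log2(fold)

    p = np.full(n_genes, np.nan)
    if tested.any():
        _, p_tested = rank_sum_test(a[tested].T, b[tested].T)
        p[tested] = p_tested
    q = bh_adjust(p)

    direction = np.full(n_genes, "ns", dtype=object)
    sig = q < alpha  # NaN-safe: NaN < alpha is False
    direction[sig & (fold > fc_threshold)] = "up"
    direction[sig & (fold < 1.0 / fc_threshold)] = "down"

    table = pd.DataFrame(
        {
            "p_value": p,
            "p_adjusted": q,
            "log2_fold_change": log2_fc,
            "pct_A": pct_a,
            "pct_B": pct_b,
            "direction": direction,
        }
    )
    if gene_ids is not None:
        table.index = pd.Index(gene_ids, name="gene_id")
    return table


def overlap_fraction(
    de_a: pd.DataFrame, de_b: pd.DataFrame
) -> dict[str, float | None]:
    """Jaccard overlap of significant gene sets between two DE tables.

    Returns ``{"all": ..., "up": ..., "down": ...}`` with ``None`` where the
    union is empty. Tables must share a gene universe (index).
    """
    if not de_a.index.equals(de_b.index):
        raise ValueError("DE tables must share the same gene universe")

    def jaccard(sel_a: pd.Series, sel_b: pd.Series) -> float | None:
        set_a = set(de_a.index[sel_a])
        set_b = set(de_b.index[sel_b])
        union = set_a | set_b
        if not union:
            return None
        return len(set_a & set_b) / len(union)

    return {
        "all": jaccard(de_a["direction"] != "ns", de_b["direction"] != "ns"),
        "up": jaccard(de_a["direction"] == "up", de_b["direction"] == "up"),
        "down": jaccard(de_a["direction"] == "down", de_b["direction"] == "down"),
    }
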