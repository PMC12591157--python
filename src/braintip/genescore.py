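"""Per-cell gene-set activity and cohort-level composition statistics.

* :func:`auc_score` — rank-based recovery-curve AUC per cell (the AUCell
  statistic): genes are ranked by descending expression within each cell and
  the area under the curve of set-gene recoveries within the top fraction of
  ranks is normalized so a set occupying exactly the top ranks scores 1.
* :func:`threshold_shift_score` — the "threshold reached" delta: the excess
  proportion of old cells above a young-group score quantile.
* :func:`enrichment_score` — relative abundance of a cell type in a sample,
  E = (n_A / N_A) / (N / N_total); E > 1 means over-representation.
* :func:`cv_profile` — per-group median across genes of the per-gene
  coefficient of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: tuple[str, ...]
    source: str = "custom"  # SASP | CSP | learning-memory | custom

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene set must be non-empty")

    def resolve(self, universe: list[str]) -> np.ndarray:
        """Indices of set genes in the universe; unresolvable ids dropped."""
        lookup = {g: i for i, g in enumerate(universe)}
        idx = [lookup[g] for g in self.gene_ids if g in lookup]
        missing = len(self.gene_ids) - len(idx)
        if missing:
            logger.warning("gene set %s: dropped %d unresolvable ids", self.name, missing)
        return np.asarray(sorted(set(idx)), dtype=int)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a two-column TSV (set_name, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    if not {"set_name", "gene_id"}.issubset(df.columns):
        raise ValueError("gene-set TSV needs columns set_name and gene_id")
    return [
        GeneSet(name=str(name), gene_ids=tuple(sub["gene_id"].astype(str)))
        for name, sub in df.groupby("set_name", sort=True)
    ]


def auc_score(
    norm_expr: sparse.spmatrix | np.ndarray,
    gene_set: GeneSet | np.ndarray,
    top_fraction: float = 0.05,
    *,
    gene_ids: list[str] | None = None,
) -> np.ndarray:
    """Recovery-curve AUC of a gene set per cell, in [0, 1].

    Genes are ranked per cell by descending expression, ties broken by
    ascending gene index. With k = ceil(top_fraction * n_genes), the score is
    the area under the step curve of cumulative set-gene hits over ranks
    1..k, divided by the maximal attainable area.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    x = norm_expr.toarray() if sparse.issparse(norm_expr) else np.asarray(norm_expr, float)
    n_genes, n_cells = x.shape
    if isinstance(gene_set, GeneSet):
        if gene_ids is None:
            raise ValueError("gene_ids required to resolve a named GeneSet")
        set_idx = gene_set.resolve(gene_ids)
    else:
        set_idx = np.asarray(gene_set, dtype=int)
    if set_idx.size == 0:
        raise ValueError("resolved gene set is empty")

    k = int(np.ceil(top_fraction * n_genes))
    s = set_idx.size
    # stable argsort on -expression gives descending order with ascending
    # gene-index tie-break
    order = np.argsort(-x, axis=0, kind="stable")
    rank_of_gene = np.argsort(order, axis=0, kind="stable")  # 0-based rank per gene
    set_ranks = rank_of_gene[set_idx]  # (s, n_cells)

    # area under the recovery curve evaluated at ranks 1..k:
    # each set gene at 0-based rank r < k contributes (k - r) unit columns
    contrib = np.clip(k - set_ranks, 0, None)
    area = contrib.sum(axis=0).astype(float)
    ranks_max = np.arange(1, k + 1)
    max_area = float(np.minimum(ranks_max, s).sum())
    return area / max_area


def threshold_shift_score(
    scores: np.ndarray,
    age_group: np.ndarray | pd.Series,
    quantile_q: float = 0.90,
) -> float:
    """Excess proportion of old cells above the young-score q-quantile.

    Returns ``P_old(score > t) - P_young(score > t)`` with t the
    ``quantile_q`` quantile of young-group scores; the young term is ~
    ``1 - quantile_q`` by construction.
    """
    scores = np.asarray(scores, float)
    group = np.asarray(age_group)
    young = scores[group == "young"]
    old = scores[group == "old"]
    if young.size == 0 or old.size == 0:
        raise ValueError("both young and old groups must be non-empty")
    t = np.quantile(young, quantile_q)
    return float((old > t).mean() - (young > t).mean())


def enrichment_score(n_A: float, N_A: float, N: float, N_total: float) -> float:
    """Sample-enrichment score E = (n_A / N_A) / (N / N_total)."""
    if N_A <= 0 or N <= 0 or N_total <= 0:
        raise ValueError("N_A, N and N_total must be positive")
    if n_A < 0 or n_A > min(N_A, N):
        raise ValueError("require 0 <= n_A <= min(N_A, N)")
    return (n_A / N_A) / (N / N_total)


def enrichment_table(
    meta: pd.DataFrame,
    type_col: str = "cell_type",
    sample_col: str = "donor_id",
) -> pd.DataFrame:
    """Per-sample, per-type enrichment scores over a cell metadata table."""
    n_total = len(meta)
    sample_sizes = meta.groupby(sample_col).size()
    type_sizes = meta.groupby(type_col).size()
    counts = meta.groupby([sample_col, type_col]).size()
    rows = []
    for sample, n_sample in sample_sizes.items():
        for ctype, n_type in type_sizes.items():
            n_at = int(counts.get((sample, ctype), 0))
            rows.append(
                {
                    sample_col: sample,
                    type_col: ctype,
                    "n_A": n_at,
                    "N_A": int(n_type),
                    "N": int(n_sample),
                    "N_total": n_total,
                    "E": enrichment_score(n_at, n_type, n_sample, n_total),
                }
            )
    return pd.DataFrame(rows)


def cv_profile(
    norm_expr: sparse.spmatrix | np.ndarray,
    groups: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Median across genes of the per-gene CV (SD/mean) within each group.

    Genes with zero mean in a group are skipped for that group. Groups with
    fewer than 2 cells raise.
    """
    x = norm_expr.toarray() if sparse.issparse(norm_expr) else np.asarray(norm_expr, float)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        sub = x[:, mask]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        nonzero = mean > 0
        cv = sd[nonzero] / mean[nonzero]
        rows.append({"group": g, "n_cells": int(mask.sum()),
                     "n_genes": int(nonzero.sum()), "median_cv": float(np.median(cv))})
    return pd.DataFrame(rows)
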