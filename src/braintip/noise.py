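"""Transcriptional-noise quantification.

Pipeline: (1) equalize sequencing depth across cells by binomial thinning;
(2) select expression-matched *invariant* genes — rank genes by mean
expression, split into bins, drop the extreme bins, and keep the
lowest-CV genes per retained bin; (3) quantify each cell's noise as the
Euclidean distance from its invariant-gene profile to its cell type's mean
profile; (4) compare distances between groups with rank-sum tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse

from ._stats import bh_adjust, rank_sum_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseConfig:
    n_bins: int = 10
    genes_per_bin: int = 10
    target_depth: int | None = None  # None -> minimum post-QC cell depth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 3:
            raise ValueError("n_bins must be at least 3")
        if self.genes_per_bin < 1:
            raise ValueError("genes_per_bin must be at least 1")


def downsample_counts(
    counts: sparse.spmatrix | np.ndarray,
    target_depth: int,
    seed: int = 0,
    *,
    exact: bool = False,
) -> sparse.csr_matrix:
    """Thin each cell's counts to an expected depth of ``target_depth``.

    Default mode is binomial thinning with p = target_depth / cell_depth
    (expected post-depth exactly target_depth); ``exact=True`` instead draws
    a multivariate-hypergeometric subsample of exactly ``target_depth``
    counts. Cells at or below the target pass through unchanged.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    rng = np.random.default_rng(seed)
    mat = sparse.csc_matrix(counts, dtype=np.int64)
    depth = np.asarray(mat.sum(axis=0)).ravel()
    out = mat.copy()
    for j in range(mat.shape[1]):
        d = depth[j]
        if d <= target_depth:
            continue
        start, end = out.indptr[j], out.indptr[j + 1]
        col = out.data[start:end]
        if exact:
            out.data[start:end] = rng.multivariate_hypergeometric(col, target_depth)
        else:
            out.data[start:end] = rng.binomial(col, target_depth / d)
    out.eliminate_zeros()
    return out.tocsr()


def select_invariant_genes(
    norm_expr: sparse.spmatrix | np.ndarray,
    cfg: NoiseConfig = NoiseConfig(),
    *,
    gene_ids: list[str] | None = None,
) -> np.ndarray:
    """Expression-matched low-CV gene selection.

    Genes with nonzero mean are ranked by mean expression and split into
    ``n_bins`` equal-size bins (remainder to the last bin); the first and
    last bins are dropped; within each retained bin the ``genes_per_bin``
    genes with the lowest CV are kept. Returns sorted gene indices (or ids).
    """
    x = norm_expr.toarray() if sparse.issparse(norm_expr) else np.asarray(norm_expr, float)
    mean = x.mean(axis=1)
    nonzero = np.flatnonzero(mean > 0)
    if nonzero.size < cfg.n_bins:
        raise ValueError(
            f"need at least n_bins={cfg.n_bins} genes with nonzero mean, got {nonzero.size}"
        )
    sd = x[nonzero].std(axis=1, ddof=1)
    cv = sd / mean[nonzero]
    order = np.argsort(mean[nonzero], kind="stable")  # ascending mean
    bin_size = nonzero.size // cfg.n_bins

    selected: list[int] = []
    for b in range(1, cfg.n_bins - 1):  # drop first and last bins
        members = order[b * bin_size : (b + 1) * bin_size]
        if members.size < cfg.genes_per_bin:
            logger.warning(
                "bin %d has only %d genes (< genes_per_bin=%d); taking all",
                b, members.size, cfg.genes_per_bin,
            )
            chosen = members
        else:
            chosen = members[np.argsort(cv[members], kind="stable")[: cfg.genes_per_bin]]
        selected.extend(nonzero[chosen].tolist())
    idx = np.asarray(sorted(selected), dtype=int)
    if gene_ids is not None:
        return np.asarray([gene_ids[i] for i in idx])
    return idx


def noise_distance(
    norm_expr: sparse.spmatrix | np.ndarray,
    meta: pd.DataFrame,
    invariant_genes: np.ndarray,
) -> pd.DataFrame:
    """Euclidean distance of each cell to its cell type's mean profile.

    Distances are computed over the invariant genes only. Cell types with a
    single cell are flagged (their distance is trivially 0).
    """
    if "cell_type" not in meta.columns:
        raise ValueError("metadata has no 'cell_type' column")
    invariant_genes = np.asarray(invariant_genes, dtype=int)
    if invariant_genes.size == 0:
        raise ValueError("invariant gene list is empty")
    x = norm_expr.toarray() if sparse.issparse(norm_expr) else np.asarray(norm_expr, float)
    sub = x[invariant_genes]  # (g, cells)
    types = meta["cell_type"].to_numpy()
    dist = np.empty(len(meta))
    flagged = np.zeros(len(meta), dtype=bool)
    for t in pd.unique(types):
        mask = types == t
        center = sub[:, mask].mean(axis=1)
        dist[mask] = np.sqrt(((sub[:, mask] - center[:, None]) ** 2).sum(axis=0))
        if mask.sum() == 1:
            flagged[mask] = True
            logger.warning("cell type %r has a single cell; distance is degenerate", t)
    out = meta[["cell_id", "cell_type"]].copy() if "cell_id" in meta.columns else pd.DataFrame(
        {"cell_type": types}
    )
    out["noise"] = dist
    out["single_cell_type"] = flagged
    return out


def compare_noise(
    distances: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    *,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-cell-type pairwise rank-sum comparison of noise between groups.

    Groups with fewer than ``min_cells`` cells in a cell type are excluded
    (logged). p-values are BH-adjusted across all tests performed.
    """
    groups = np.asarray(groups)
    if len(groups) != len(distances):
        raise ValueError("groups must align with the distances table")
    if pd.unique(groups).size < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for ctype in pd.unique(distances["cell_type"]):
        mask_t = distances["cell_type"].to_numpy() == ctype
        sub = distances.loc[mask_t, "noise"].to_numpy()
        sub_groups = groups[mask_t]
        present = [g for g in pd.unique(sub_groups) if (sub_groups == g).sum() >= min_cells]
        dropped = set(pd.unique(sub_groups)) - set(present)
        if dropped:
            logger.info("cell type %r: excluding small groups %s", ctype, sorted(dropped))
        for g_a, g_b in combinations(present, 2):
            a = sub[sub_groups == g_a]
            b = sub[sub_groups == g_b]
            _, p = rank_sum_test(a[:, None], b[:, None])
            rows.append(
                {
                    "cell_type": ctype,
                    "group_a": g_a,
                    "group_b": g_b,
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "p_value": float(p[0]),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out
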