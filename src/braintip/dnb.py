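"""Dynamic-network-biomarker (DNB) scoring and tipping-point location.

DNB theory holds that just before a system crosses a critical transition, a
small group of variables (the dominant module) shows three concurrent
signatures: sharply increased variance, sharply increased intra-module
correlation, and decreased correlation with everything outside the module.
The composite index

    CI = (PCC_in / PCC_out) * SD_in

condenses the three criteria: SD_in is the mean within-state per-gene
standard deviation over module genes, PCC_in the mean absolute pairwise
Pearson correlation inside the module, and PCC_out the mean absolute
correlation between module and non-module genes. Cells are partitioned into
ordered states along age or pseudotime; the state whose dominant module
attains the highest CI is called the tipping point, and cells in earlier /
later states are labelled young / old.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

PCC_OUT_FLOOR = 1e-6

# default age-bin edges (inclusive on both ends); the 50-55 / 56-60 / 65-70
# bins mirror the named comparison groups, the rest tile the cohort range
DEFAULT_AGE_BINS: tuple[tuple[int, int], ...] = (
    (29, 41), (42, 49), (50, 55), (56, 60), (61, 64),
    (65, 70), (71, 77), (78, 83), (84, 89), (90, 94),
)


@dataclass(frozen=True)
class State:
    state_id: str
    order: int
    interval: tuple[float, float]
    cell_index: tuple[int, ...]  # positional indices into the metadata/matrix


@dataclass
class StateClustering:
    states: list[State]
    mode: str  # "pseudotime" | "age"

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for s in self.states:
            overlap = seen.intersection(s.cell_index)
            if overlap:
                raise ValueError("states are not disjoint")
            seen.update(s.cell_index)
        orders = [s.order for s in self.states]
        if orders != sorted(orders):
            raise ValueError("states must be ordered along the axis")


@dataclass(frozen=True)
class GeneModule:
    gene_idx: tuple[int, ...]
    state_id: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.gene_idx)) != len(self.gene_idx):
            raise ValueError("module members must be unique")


@dataclass
class DNBScore:
    state_id: str
    module: GeneModule
    sd_in: float
    pcc_in: float
    pcc_out: float
    ci: float


@dataclass
class TippingReport:
    scores: dict[str, DNBScore]  # dominant score per scorable state
    tipping_state: str
    age_histogram: dict[str, int]
    modal_age_bin: str | None
    labels: pd.DataFrame  # cell_id (if known), state_id, label
    dnb_genes: list[int]
    boundary_warning: bool

    def to_json(self, path: str | Path, gene_ids: list[str] | None = None) -> None:
        payload = {
            "tipping_state": self.tipping_state,
            "modal_age_bin": self.modal_age_bin,
            "boundary_warning": self.boundary_warning,
            "age_histogram": self.age_histogram,
            "states": {
                sid: {
                    "sd_in": s.sd_in,
                    "pcc_in": s.pcc_in,
                    "pcc_out": s.pcc_out,
                    "ci": s.ci,
                    "module_size": len(s.module.gene_idx),
                }
                for sid, s in self.scores.items()
            },
            "dnb_genes": (
                [gene_ids[i] for i in self.dnb_genes] if gene_ids else list(self.dnb_genes)
            ),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------


def bin_states(
    meta: pd.DataFrame,
    mode: str = "age",
    n_states: int = 10,
    bin_edges: tuple[tuple[float, float], ...] | None = None,
) -> StateClustering:
    """Partition cells into ordered states along age or pseudotime.

    Age mode uses closed bins (default :data:`DEFAULT_AGE_BINS`); pseudotime
    mode uses equal-frequency quantile bins. Cells outside every age bin are
    left out of the clustering (they are ineligible).
    """
    if mode not in ("age", "pseudotime"):
        raise ValueError("mode must be 'age' or 'pseudotime'")
    if mode not in meta.columns:
        raise ValueError(f"metadata has no {mode!r} column")
    axis = meta[mode]
    if axis.isna().any():
        raise ValueError(f"column {mode!r} contains missing values")
    axis = axis.to_numpy(float)

    states: list[State] = []
    if mode == "age":
        edges = bin_edges if bin_edges is not None else DEFAULT_AGE_BINS
        for order, (lo, hi) in enumerate(edges):
            idx = np.flatnonzero((axis >= lo) & (axis <= hi))
            if idx.size:
                states.append(
                    State(f"[{lo:g},{hi:g}]", order, (float(lo), float(hi)), tuple(idx))
                )
    else:
        qs = np.quantile(axis, np.linspace(0, 1, n_states + 1))
        ranks = np.argsort(np.argsort(axis, kind="stable"), kind="stable")
        # equal-frequency assignment by rank, robust to tied quantile edges
        bins = np.minimum(ranks * n_states // len(axis), n_states - 1)
        for order in range(n_states):
            idx = np.flatnonzero(bins == order)
            if idx.size:
                states.append(
                    State(
                        f"PT{order}",
                        order,
                        (float(qs[order]), float(qs[order + 1])),
                        tuple(idx),
                    )
                )
    return StateClustering(states=states, mode=mode)


def _abs_corr(x: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between rows; zero-variance rows give 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    return np.abs(r)


def cluster_gene_modules(
    expr_state: np.ndarray | sparse.spmatrix,
    min_module_size: int = 10,
    cut_height: float = 0.75,
    top_sd_genes: int | None = None,
) -> list[GeneModule]:
    """Detect co-expression modules within a state.

    Average-linkage hierarchical clustering of genes on distance 1 - |r|,
    tree cut at ``cut_height``; clusters of size >= ``min_module_size`` are
    returned (largest first). Zero-variance genes are excluded beforehand.
    ``top_sd_genes`` restricts clustering to the genes with the highest
    within-state SD — the first DNB criterion — which is essential for
    replicate-level cohorts where correlation estimates are noisy.
    """
    x = expr_state.toarray() if sparse.issparse(expr_state) else np.asarray(expr_state, float)
    sd = x.std(axis=1)
    variable = np.flatnonzero(sd > 0)
    if top_sd_genes is not None and variable.size > top_sd_genes:
        variable = variable[np.argsort(sd[variable], kind="stable")[-top_sd_genes:]]
        variable.sort()
    if variable.size < 2:
        raise ValueError("fewer than 2 genes with nonzero within-state variance")
    dist = 1.0 - _abs_corr(x[variable])
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    tree = linkage(condensed, method="average")
    assignments = fcluster(tree, t=cut_height, criterion="distance")
    modules = []
    for label in np.unique(assignments):
        members = variable[assignments == label]
        if members.size >= min_module_size:
            modules.append(GeneModule(gene_idx=tuple(int(i) for i in members)))
    modules.sort(key=lambda m: (-len(m.gene_idx), m.gene_idx))
    return modules


def _score_module(
    abs_r: np.ndarray, gene_sd: np.ndarray, module: GeneModule, state_id: str
) -> DNBScore:
    n_genes = abs_r.shape[0]
    idx = np.asarray(module.gene_idx, dtype=int)
    if idx.size < 2:
        raise ValueError("module must contain at least 2 genes")
    outside = np.setdiff1d(np.arange(n_genes), idx)
    if outside.size == 0:
        raise ValueError("module covers the full gene set; PCC_out undefined")
    sd_in = float(gene_sd[idx].mean())
    within = abs_r[np.ix_(idx, idx)]
    m = idx.size
    # off-diagonal mean; diagonal of |r| is 1 except for zero-variance genes
    pcc_in = float((within.sum() - np.trace(within)) / (m * (m - 1)))
    pcc_out = float(abs_r[np.ix_(idx, outside)].mean())
    ci = (pcc_in / max(pcc_out, PCC_OUT_FLOOR)) * sd_in
    return DNBScore(
        state_id=state_id, module=module, sd_in=sd_in,
        pcc_in=pcc_in, pcc_out=pcc_out, ci=float(ci),
    )


def compute_ci(
    expr_state: np.ndarray | sparse.spmatrix,
    module: GeneModule,
    state_id: str = "",
) -> DNBScore:
    """Composite index of a module within one state.

    SD_in: mean per-gene sample SD (ddof=1) over module genes; PCC_in: mean
    |r| over all within-module gene pairs; PCC_out: mean |r| over all
    module × non-module pairs, floored at 1e-6; CI = (PCC_in/PCC_out)*SD_in.
    """
    x = expr_state.toarray() if sparse.issparse(expr_state) else np.asarray(expr_state, float)
    return _score_module(_abs_corr(x), x.std(axis=1, ddof=1), module, state_id)


def score_states(
    norm_expr: np.ndarray | sparse.spmatrix,
    states: StateClustering,
    min_module_size: int = 10,
    cut_height: float = 0.75,
    min_state_cells: int | None = None,
    top_sd_genes: int | None = None,
) -> dict[str, DNBScore]:
    """Dominant (max-CI) module score per state.

    States with fewer than ``min_state_cells`` units (default twice
    ``min_module_size``; set lower for replicate-level bulk cohorts) or with
    no detected module are skipped with a log message. CI ties break toward
    the larger module, then lexicographically smaller gene-index tuple.
    """
    x = norm_expr.toarray() if sparse.issparse(norm_expr) else np.asarray(norm_expr, float)
    if min_state_cells is None:
        min_state_cells = 2 * min_module_size
    scores: dict[str, DNBScore] = {}
    for state in states.states:
        cells = np.asarray(state.cell_index, int)
        if cells.size < min_state_cells:
            logger.info("state %s skipped: %d cells", state.state_id, cells.size)
            continue
        sub = x[:, cells]
        try:
            modules = cluster_gene_modules(sub, min_module_size, cut_height, top_sd_genes)
        except ValueError as exc:
            logger.info("state %s skipped: %s", state.state_id, exc)
            continue
        if not modules:
            logger.info("state %s skipped: no module of size >= %d", state.state_id, min_module_size)
            continue
        abs_r = _abs_corr(sub)
        gene_sd = sub.std(axis=1, ddof=1)
        best: DNBScore | None = None
        for module in modules:
            if len(module.gene_idx) >= x.shape[0]:
                logger.info(
                    "state %s: module covers the full gene universe, unscorable",
                    state.state_id,
                )
                continue
            score = _score_module(
                abs_r, gene_sd, dataclasses.replace(module, state_id=state.state_id),
                state.state_id,
            )
            if (
                best is None
                or score.ci > best.ci
                or (
                    score.ci == best.ci
                    and (
                        len(score.module.gene_idx) > len(best.module.gene_idx)
                        or (
                            len(score.module.gene_idx) == len(best.module.gene_idx)
                            and score.module.gene_idx < best.module.gene_idx
                        )
                    )
                )
            ):
                best = score
        if best is not None:
            scores[state.state_id] = best
    if not scores:
        raise ValueError("no scorable states")
    return scores


def locate_tipping_point(
    scores: dict[str, DNBScore],
    states: StateClustering,
    meta: pd.DataFrame,
    age_bins: tuple[tuple[float, float], ...] = DEFAULT_AGE_BINS,
) -> TippingReport:
    """Identify the tipping state (argmax CI) and label cells young/tipping/old.

    Ties in CI break toward the earlier state order. The age-bin histogram
    summarises the donor ages of tipping-state cells; the modal bin is its
    argmax.
    """
    order_of = {s.state_id: s.order for s in states.states}
    scored = [sid for sid in scores]
    if len(scored) < 3:
        raise ValueError("need at least 3 scorable states to label young/tipping/old")
    tipping = max(scored, key=lambda sid: (scores[sid].ci, -order_of[sid]))
    tip_order = order_of[tipping]
    orders = sorted(order_of[sid] for sid in scored)
    boundary = tip_order == orders[0] or tip_order == orders[-1]
    if boundary:
        logger.warning("tipping state %s is at the boundary of the state order", tipping)

    rows = []
    for state in states.states:
        if state.order < tip_order:
            label = "young"
        elif state.order == tip_order:
            label = "tipping"
        else:
            label = "old"
        for i in state.cell_index:
            rows.append((i, state.state_id, label))
    labels = pd.DataFrame(rows, columns=["cell_index", "state_id", "label"])
    if "cell_id" in meta.columns:
        labels.insert(0, "cell_id", meta["cell_id"].to_numpy()[labels["cell_index"]])

    hist: dict[str, int] = {}
    modal = None
    if "age" in meta.columns:
        tip_cells = labels.loc[labels["label"] == "tipping", "cell_index"].to_numpy()
        ages = meta["age"].to_numpy(float)[tip_cells]
        for lo, hi in age_bins:
            hist[f"[{lo:g},{hi:g}]"] = int(((ages >= lo) & (ages <= hi)).sum())
        if any(hist.values()):
            modal = max(hist, key=lambda k: hist[k])

    return TippingReport(
        scores=scores,
        tipping_state=tipping,
        age_histogram=hist,
        modal_age_bin=modal,
        labels=labels,
        dnb_genes=sorted(scores[tipping].module.gene_idx),
        boundary_warning=boundary,
    )


def export_network(
    expr_state: np.ndarray | sparse.spmatrix,
    module: GeneModule,
    r_threshold: float = 0.3,
    *,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Within-state correlation network around a module.

    Nodes are the module genes plus outside genes whose mean |r| to the
    module exceeds ``r_threshold``; edges are node pairs with |r| >=
    ``r_threshold``, weighted by the signed correlation.
    """
    x = expr_state.toarray() if sparse.issparse(expr_state) else np.asarray(expr_state, float)
    idx = np.asarray(module.gene_idx, int)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.nan_to_num(np.corrcoef(x), nan=0.0)
    outside = np.setdiff1d(np.arange(x.shape[0]), idx)
    attached = outside[np.abs(r[np.ix_(outside, idx)]).mean(axis=1) > r_threshold] \
        if outside.size else np.array([], int)
    nodes = np.concatenate([idx, attached])
    nodes.sort()
    rows = []
    for a_pos in range(len(nodes)):
        for b_pos in range(a_pos + 1, len(nodes)):
            a, b = nodes[a_pos], nodes[b_pos]
            if abs(r[a, b]) >= r_threshold:
                rows.append((int(a), int(b), float(r[a, b])))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
    if edges.empty:
        logger.info("network export: no edges at threshold %.3g", r_threshold)
    if gene_ids is not None and not edges.empty:
        edges["gene_a"] = [gene_ids[i] for i in edges["gene_a"]]
        edges["gene_b"] = [gene_ids[i] for i in edges["gene_b"]]
    return edges
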