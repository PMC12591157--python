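"""Sliding-window differential-expression scan over age (DE-SWAN).

For each window center *c*, units (donor pseudobulks by default) with age in
``[c - w/2, c]`` form the younger group and units with age in ``(c, c + w/2]``
the older group; the per-gene two-sided Wilcoxon rank-sum test is applied
and the numbers of genes significant at raw p and BH q below ``alpha`` are
recorded. Peaks of the resulting profile mark ages of concentrated
molecular dysregulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from ._stats import bh_adjust, rank_sum_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SwanConfig:
    window_width: float = 20.0
    centers: tuple[float, ...] | None = None  # None -> all distinct unit ages
    alpha: float = 0.05
    min_group: int = 3
    unit: str = "donor"  # donor-pseudobulk ("donor") or "cell"

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if self.min_group < 1:
            raise ValueError("min_group must be at least 1")
        if self.unit not in ("donor", "cell"):
            raise ValueError("unit must be 'donor' or 'cell'")
        if self.centers is not None and len(self.centers) == 0:
            raise ValueError("centers, when given, must be non-empty")


def pseudobulk(
    norm_expr: sparse.spmatrix | np.ndarray,
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor mean of normalized expression.

    Returns (donor × gene matrix, donor metadata with age and sex). Donors
    with no cells are dropped with a warning.
    """
    if "donor_id" not in meta.columns:
        raise ValueError("metadata has no 'donor_id' column")
    x = norm_expr.toarray() if sparse.issparse(norm_expr) else np.asarray(norm_expr, float)
    if x.shape[1] != len(meta):
        raise ValueError("expression and metadata disagree on cell count")
    donors = meta["donor_id"].to_numpy()
    order = pd.unique(donors)
    profiles = np.empty((len(order), x.shape[0]))
    rows = []
    for i, d in enumerate(order):
        mask = donors == d
        profiles[i] = x[:, mask].mean(axis=1)
        sub = meta.loc[mask]
        rows.append(
            {
                "donor_id": d,
                "age": float(sub["age"].iloc[0]),
                "sex": sub["sex"].iloc[0] if "sex" in sub else None,
                "n_cells": int(mask.sum()),
            }
        )
    all_donors = meta["donor_id"].nunique()
    if len(order) < all_donors:  # pragma: no cover - defensive
        logger.warning("dropped %d donors with zero cells", all_donors - len(order))
    unit_matrix = pd.DataFrame(profiles, index=pd.Index(order, name="donor_id"))
    return unit_matrix, pd.DataFrame(rows)


def deswan_profile(
    unit_matrix: pd.DataFrame | np.ndarray,
    ages: np.ndarray | pd.Series,
    cfg: SwanConfig = SwanConfig(),
) -> pd.DataFrame:
    """Significant-gene counts per sliding-window center.

    ``unit_matrix`` is units × genes; ``ages`` gives each unit's age. Centers
    with fewer than ``min_group`` units on either side are marked skipped
    with zero counts.
    """
    x = unit_matrix.to_numpy() if isinstance(unit_matrix, pd.DataFrame) else np.asarray(unit_matrix, float)
    ages = np.asarray(ages, float)
    if ages.size != x.shape[0]:
        raise ValueError("ages length must match the number of units")
    if np.unique(ages).size < 2:
        raise ValueError("need at least 2 distinct ages")
    centers = (
        np.asarray(cfg.centers, float)
        if cfg.centers is not None
        else np.unique(ages)
    )
    if centers.size == 0:
        raise ValueError("empty centers list")
    half = cfg.window_width / 2.0

    rows = []
    for c in centers:
        low = (ages >= c - half) & (ages <= c)
        high = (ages > c) & (ages <= c + half)
        n_low, n_high = int(low.sum()), int(high.sum())
        if n_low < cfg.min_group or n_high < cfg.min_group:
            rows.append((c, n_low, n_high, 0, 0, True))
            continue
        _, p = rank_sum_test(x[low], x[high])
        q = bh_adjust(p)
        rows.append(
            (c, n_low, n_high, int((p < cfg.alpha).sum()), int((q < cfg.alpha).sum()), False)
        )
    return pd.DataFrame(
        rows,
        columns=["center", "n_low", "n_high", "n_significant_p", "n_significant_q", "skipped"],
    )


def find_peaks(
    profile: pd.DataFrame, column: str = "n_significant_p"
) -> list[tuple[float, int]]:
    """Local maxima of the profile over non-skipped centers.

    A peak is strictly greater than both neighbours (endpoints need only
    beat their single neighbour); a plateau contributes its leftmost center.
    Returned sorted by height descending, ties by center ascending.
    """
    sub = profile.loc[~profile["skipped"]].sort_values("center")
    if sub.empty:
        raise ValueError("all centers skipped")
    centers = sub["center"].to_numpy()
    heights = sub[column].to_numpy()

    # compress runs of equal height; a run is a peak if strictly above both
    # neighbouring runs (missing neighbour counts as below)
    run_starts = [0]
    for i in range(1, len(heights)):
        if heights[i] != heights[i - 1]:
            run_starts.append(i)
    run_heights = [heights[i] for i in run_starts]
    peaks = []
    for r, h in enumerate(run_heights):
        left_ok = r == 0 or run_heights[r - 1] < h
        right_ok = r == len(run_heights) - 1 or run_heights[r + 1] < h
        if left_ok and right_ok and len(run_heights) > 1:
            peaks.append((float(centers[run_starts[r]]), int(h)))
    peaks.sort(key=lambda t: (-t[1], t[0]))
    return peaks
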