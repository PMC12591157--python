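"""Nucleus-level quality control, library-size normalization, age groups.

Filters follow the strict-inequality convention: a nucleus is removed when
its detected-feature count is *less than* ``min_features`` or *more than*
``max_features``, or when *more than* ``max_mito_fraction`` of its counts
map to mitochondrial genes; boundary values are kept.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .synthetic import CountMatrix


@dataclass(frozen=True)
class QCConfig:
    min_features: int = 500
    max_features: int = 7500
    max_mito_fraction: float = 0.05
    target_scale: float = 1e4

    def __post_init__(self) -> None:
        if not 0 < self.min_features <= self.max_features:
            raise ValueError("require 0 < min_features <= max_features")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.target_scale <= 0:
            raise ValueError("target_scale must be positive")


@dataclass
class QCReport:
    input_cells: int
    removed_low_features: int
    removed_high_features: int
    removed_mito: int
    output_cells: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def filter_nuclei(
    counts: CountMatrix,
    meta: pd.DataFrame,
    cfg: QCConfig = QCConfig(),
) -> tuple[CountMatrix, pd.DataFrame, QCReport]:
    """Remove low/high-complexity nuclei and high-mitochondrial nuclei.

    Detected features are genes with count > 0. A cell failing the feature
    rule is attributed to that rule even if it also fails the mitochondrial
    rule. Idempotent: running twice removes nothing new.
    """
    is_mito = np.array([g.startswith("MT-") for g in counts.gene_ids])
    if not is_mito.any() and cfg.max_mito_fraction < 1.0:
        raise ValueError(
            "no mitochondrial genes flagged (MT- prefix) but a mitochondrial "
            "fraction filter is requested"
        )
    mat = counts.values.tocsc()
    mat.eliminate_zeros()
    n_cells = mat.shape[1]
    detected = mat.getnnz(axis=0)
    total = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    mito = np.asarray(mat[is_mito].sum(axis=0)).ravel().astype(float) if is_mito.any() \
        else np.zeros(n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1.0), 0.0)

    low = detected < cfg.min_features
    high = detected > cfg.max_features
    mito_bad = mito_frac > cfg.max_mito_fraction
    keep = ~(low | high | mito_bad)

    report = QCReport(
        input_cells=n_cells,
        removed_low_features=int(low.sum()),
        removed_high_features=int((high & ~low).sum()),
        removed_mito=int((mito_bad & ~low & ~high).sum()),
        output_cells=int(keep.sum()),
    )
    kept_idx = np.flatnonzero(keep)
    filtered = CountMatrix(
        values=sparse.csr_matrix(mat[:, kept_idx]),
        gene_ids=list(counts.gene_ids),
        cell_ids=[counts.cell_ids[i] for i in kept_idx],
    )
    filtered_meta = meta.iloc[kept_idx].reset_index(drop=True)
    return filtered, filtered_meta, report


def normalize_log(
    counts: CountMatrix | sparse.spmatrix | np.ndarray,
    cfg: QCConfig = QCConfig(),
) -> sparse.csr_matrix:
    """Library-size normalization to ``target_scale`` counts/cell, then ln(1+x).

    All-zero cells map to all-zero columns. Returns a sparse genes × cells
    matrix of floats.
    """
    mat = counts.values if isinstance(counts, CountMatrix) else counts
    mat = sparse.csc_matrix(mat, dtype=float)
    depth = np.asarray(mat.sum(axis=0)).ravel()
    scale = np.where(depth > 0, cfg.target_scale / np.maximum(depth, 1e-300), 0.0)
    mat = sparse.csc_matrix(mat.multiply(scale[None, :]))
    mat.data = np.log1p(mat.data)
    return mat.tocsr()


def assign_age_groups(meta: pd.DataFrame) -> pd.DataFrame:
    """Label cells young (ages 29–60), old (65–94) or unassigned (between).

    The dichotomy follows the convention of treating 29–60 as the adult
    group and 65–94 as the elderly group.
    """
    if "age" not in meta.columns:
        raise ValueError("metadata has no 'age' column")
    age = meta["age"]
    if age.isna().any():
        raise ValueError("age contains missing values")
    if (age < 0).any():
        raise ValueError("age contains negative values")
    group = np.full(len(meta), "unassigned", dtype=object)
    group[(age >= 29) & (age <= 60)] = "young"
    group[(age >= 65) & (age <= 94)] = "old"
    out = meta.copy()
    out["age_group"] = group
    return out
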