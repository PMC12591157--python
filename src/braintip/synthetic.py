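"""Seeded synthetic cohorts with planted ground truth.

Two generators are provided:

* :func:`generate_cohort` — an age-structured human single-nucleus cohort:
  negative-binomial UMI counts over a grid of donor ages, with optional
  planted structure of two kinds:

  - *dysregulation waves* (:class:`WaveSpec`): a set of genes whose mean
    expression shifts sigmoidally with donor age around a chosen center age,
    the single-cell analogue of the "waves of change" seen in aging plasma
    proteomes;
  - *a critical transition* (:class:`TransitionSpec`): a gene module that,
    inside one designated age or pseudotime state, has its per-gene standard
    deviation inflated and its intra-module correlation raised while staying
    near-uncorrelated with everything else — exactly the signature a
    dynamic-network-biomarker scan is meant to detect.

* :func:`generate_mouse_cohort` — a bulk RNA-seq cohort over a grid of ages
  in months with a transition module planted in one month group, emulating a
  cross-sectional mouse validation cohort.

Correlation is planted through a Gaussian copula with one shared latent
factor per module, which controls pairwise correlation while preserving the
negative-binomial marginals. Baseline co-expression "programs" (modest-rho
modules present at every age) are generated by the same mechanism so that
module detection has non-trivial structure to find in every state, as real
transcriptomes do.

All randomness flows from a single ``numpy.random.default_rng(seed)`` per
generation call; identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite

# The study cohort: 29 distinct donor ages between 29 and 94 years, with a
# gap between 29 and 42 (no donors in the thirties).
DEFAULT_AGE_GRID: tuple[int, ...] = (
    29, 42, 44, 46, 48, 50, 52, 54, 56, 58, 60, 62, 64, 66, 68,
    70, 72, 74, 76, 78, 79, 81, 83, 85, 87, 89, 91, 93, 94,
)

DEFAULT_CELL_TYPES: tuple[tuple[str, float, float], ...] = (
    # (name, baseline proportion at the grid midpoint, slope per decade)
    ("excitatory_neurons", 0.25, -0.020),
    ("inhibitory_neurons", 0.12, -0.010),
    ("oligodendrocytes", 0.25, 0.012),
    ("astrocytes", 0.18, 0.008),
    ("microglia", 0.12, 0.012),
    ("OPCs", 0.08, -0.002),
)

REQUIRED_CELL_COLUMNS = (
    "cell_id", "donor_id", "age", "sex", "region", "cell_type", "pseudotime",
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic human single-nucleus cohort."""

    age_grid: tuple[int, ...] = DEFAULT_AGE_GRID
    donors_per_age: int = 1
    cells_per_donor: int = 200
    n_genes: int = 2000
    cell_types: tuple[tuple[str, float, float], ...] = DEFAULT_CELL_TYPES
    sex_ratio: float = 14.0 / 45.0  # fraction female
    mito_gene_fraction: float = 0.01
    nb_mean_log_mu: float = -0.7
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 2.0
    depth_log_sigma: float = 0.25
    # baseline co-expression programs present at every age: (size, rho)
    background_modules: tuple[tuple[int, float], ...] = (
        (20, 0.4), (20, 0.4), (20, 0.4),
    )
    # floor on the baseline mean of genes carrying planted correlation
    # (transition module and background programs): correlation planted in
    # near-zero-count genes is invisible after the count layer, so module
    # genes are kept at measurable expression
    corr_gene_min_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        ages = tuple(self.age_grid)
        if len(ages) == 0:
            raise ValueError("age_grid must be non-empty")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("age_grid must be strictly increasing")
        if self.donors_per_age < 1 or self.cells_per_donor < 1 or self.n_genes < 1:
            raise ValueError("counts parameters must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.mito_gene_fraction <= 1.0:
            raise ValueError("mito_gene_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    @property
    def n_mito(self) -> int:
        return int(np.ceil(self.mito_gene_fraction * self.n_genes))

    def cell_type_proportions(self, age: float) -> np.ndarray:
        """Cell-type mixing proportions at a given age.

        Baselines drift linearly per decade around the grid midpoint, are
        clipped to [0, 1] and renormalized to sum to one.
        """
        mid = 0.5 * (self.age_grid[0] + self.age_grid[-1])
        p = np.array(
            [max(0.0, min(1.0, b + s * (age - mid) / 10.0))
             for _, b, s in self.cell_types]
        )
        total = p.sum()
        if total <= 0:
            raise ValueError(f"all cell-type proportions vanish at age {age}")
        return p / total


@dataclass(frozen=True)
class WaveSpec:
    """A sigmoidal age-centred shift in the mean expression of a gene set."""

    center_age: float
    gene_ids: frozenset[int]
    log2_effect: float = 1.0
    steepness: float = 0.5  # logistic slope per year
    direction: str = "up"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if not self.gene_ids:
            raise ValueError("wave gene set must be non-empty")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")

    def log2_shift(self, age: np.ndarray) -> np.ndarray:
        """Per-age log2 shift of wave-gene means (0 well before the center,
        ±log2_effect well after)."""
        s = self.log2_effect / (1.0 + np.exp(-self.steepness * (np.asarray(age, float) - self.center_age)))
        return s if self.direction == "up" else -s


@dataclass(frozen=True)
class TransitionSpec:
    """A planted critical-transition module.

    Inside ``state_interval`` (on the chosen axis) the module genes share a
    latent factor realizing ``rho_in_state`` pairwise correlation and have
    their per-gene SD inflated by ``sd_inflation``; everywhere else they
    correlate at ``rho_baseline``. Module-to-outside correlation is bounded
    by ``rho_out`` (0 = independent, the default and only planted value).
    """

    state_interval: tuple[float, float]
    module_gene_ids: frozenset[int]
    sd_inflation: float = 3.0
    rho_in_state: float = 0.7
    rho_baseline: float = 0.2
    rho_out: float = 0.0
    axis: str = "age"  # age | pseudotime

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_gene_ids", frozenset(self.module_gene_ids))
        lo, hi = self.state_interval
        if hi < lo:
            raise ValueError("state_interval must satisfy lo <= hi")
        if not self.module_gene_ids:
            raise ValueError("module gene set must be non-empty")
        if self.sd_inflation <= 1.0:
            raise ValueError("sd_inflation must exceed 1")
        if not (0.0 <= self.rho_out <= self.rho_baseline < self.rho_in_state < 1.0):
            raise ValueError("require rho_in_state > rho_baseline >= rho_out >= 0")
        if self.axis not in ("age", "pseudotime"):
            raise ValueError("axis must be 'age' or 'pseudotime'")

    def contains(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.state_interval
        x = np.asarray(x, float)
        return (x >= lo) & (x <= hi)


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene × cell UMI matrix."""

    values: sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match id lists "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("count matrix has negative entries")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids contain duplicates")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PlantedTruth:
    """Record of everything planted into a synthetic cohort (the test oracle)."""

    wave_centers: tuple[float, ...]
    wave_gene_ids: tuple[tuple[int, ...], ...]
    module_gene_ids: tuple[int, ...]
    tipping_state: tuple[float, float] | None
    background_gene_ids: tuple[tuple[int, ...], ...]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            wave_centers=tuple(d["wave_centers"]),
            wave_gene_ids=tuple(tuple(g) for g in d["wave_gene_ids"]),
            module_gene_ids=tuple(d["module_gene_ids"]),
            tipping_state=tuple(d["tipping_state"]) if d["tipping_state"] else None,
            background_gene_ids=tuple(tuple(g) for g in d["background_gene_ids"]),
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# sampling helpers


def _nb_size_p(mu: np.ndarray, theta: float | np.ndarray):
    """Numpy/scipy NB parameterisation from mean and dispersion theta
    (Var = mu + mu^2/theta)."""
    theta = np.asarray(theta, float)
    return theta, theta / (theta + mu)


def _inflated_theta(mu: np.ndarray, theta: float, s: float) -> np.ndarray:
    """Dispersion giving per-gene SD inflated by factor ``s`` at the same mean."""
    var = mu + mu**2 / theta
    target = s**2 * var
    return mu**2 / (target - mu)


def _copula_nb(
    rng: np.random.Generator,
    mu: np.ndarray,
    theta: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Draw NB counts for a gene module with shared-factor correlation rho.

    ``mu``/``theta`` have shape (n_module_genes, n_cells); a single latent
    factor per cell induces pairwise latent correlation rho, mapped through
    the Gaussian copula onto the NB marginals.
    """
    g, c = mu.shape
    if rho > 0:
        f = rng.standard_normal(c)
        z = np.sqrt(rho) * f[None, :] + np.sqrt(1.0 - rho) * rng.standard_normal((g, c))
    else:
        z = rng.standard_normal((g, c))
    u = stats.norm.cdf(z)
    size, p = _nb_size_p(mu, theta)
    counts = stats.nbinom.ppf(u, size, p)
    return counts.astype(np.int64)


def _gene_names(n_genes: int, n_mito: int) -> list[str]:
    width = len(str(max(n_genes - 1, 1)))
    names = []
    for i in range(n_genes):
        stem = f"G{i:0{width}d}"
        names.append(f"MT-{stem}" if i < n_mito else stem)
    return names


# ---------------------------------------------------------------------------
# human cohort


def generate_cohort(
    spec: CohortSpec,
    waves: list[WaveSpec] | None = None,
    transition: TransitionSpec | None = None,
) -> tuple[CountMatrix, pd.DataFrame, PlantedTruth]:
    """Generate a seeded human single-nucleus cohort with planted truth.

    Returns the UMI count matrix (genes × cells), per-cell metadata
    (donor, age, sex, region, cell type, pseudotime) and a
    :class:`PlantedTruth` record.
    """
    waves = list(waves or [])
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_genes
    n_mito = spec.n_mito
    ages = np.asarray(spec.age_grid, float)

    lo, hi = ages[0], ages[-1]
    for w in waves:
        if not (lo <= w.center_age <= hi):
            raise ValueError(f"wave center {w.center_age} outside the age grid hull")
        if max(w.gene_ids) >= n_genes or min(w.gene_ids) < 0:
            raise ValueError("wave gene ids out of range")

    wave_gene_union: set[int] = set().union(*[w.gene_ids for w in waves]) if waves else set()
    module_ids: set[int] = set(transition.module_gene_ids) if transition else set()
    if transition:
        if max(module_ids) >= n_genes or min(module_ids) < 0:
            raise ValueError("transition module gene ids out of range")
        if module_ids & wave_gene_union:
            raise ValueError("wave gene sets overlap the transition module (confounded truth)")
        if any(i < n_mito for i in module_ids):
            raise ValueError("transition module overlaps mitochondrial genes")
        if transition.axis == "age":
            t_lo, t_hi = transition.state_interval
            if t_hi < lo or t_lo > hi:
                raise ValueError("transition interval lies outside the age grid")

    # baseline co-expression programs take the top end of the gene index range
    background: list[list[int]] = []
    next_idx = n_genes
    for size, rho in spec.background_modules:
        block = list(range(next_idx - size, next_idx))
        next_idx -= size
        if min(block) < n_mito:
            raise ValueError("background modules exceed available genes")
        if set(block) & (wave_gene_union | module_ids):
            raise ValueError(
                "background modules (top gene indices) overlap wave/transition genes; "
                "choose wave/module gene ids below "
                f"{n_genes - sum(s for s, _ in spec.background_modules)}"
            )
        background.append(block)

    base_mu = rng.lognormal(spec.nb_mean_log_mu, spec.nb_mean_log_sigma, n_genes)
    corr_genes = sorted(module_ids.union(*background)) if (module_ids or background) else []
    if corr_genes:
        base_mu[corr_genes] = np.maximum(base_mu[corr_genes], spec.corr_gene_min_mean)

    # donor table
    donors = []
    for age in spec.age_grid:
        for d in range(spec.donors_per_age):
            donors.append(
                {
                    "donor_id": f"D{int(age):03d}_{d}",
                    "age": float(age),
                    "sex": "F" if rng.random() < spec.sex_ratio else "M",
                    "region": "cortex" if rng.random() < 0.5 else "hippocampus",
                }
            )
    donor_df = pd.DataFrame(donors)

    type_names = [name for name, _, _ in spec.cell_types]
    cells = []
    for _, donor in donor_df.iterrows():
        props = spec.cell_type_proportions(donor["age"])
        types = rng.choice(len(type_names), size=spec.cells_per_donor, p=props)
        for t in types:
            cells.append((donor["donor_id"], donor["age"], donor["sex"], donor["region"], type_names[t]))
    meta = pd.DataFrame(cells, columns=["donor_id", "age", "sex", "region", "cell_type"])
    n_cells = len(meta)
    meta.insert(0, "cell_id", [f"C{i:06d}" for i in range(n_cells)])
    # pseudotime: monotone in age with per-cell jitter, scaled to [0, 1]
    pt = (meta["age"].to_numpy() - lo) / (hi - lo) + rng.normal(0.0, 0.02, n_cells)
    meta["pseudotime"] = np.clip(pt, 0.0, None)

    cell_age = meta["age"].to_numpy()
    depth_factor = rng.lognormal(0.0, spec.depth_log_sigma, n_cells)

    # per-cell mean matrix modifiers from waves (per distinct age, cheap)
    log2_shift = np.zeros((n_genes, len(ages)))
    for w in waves:
        shift = w.log2_shift(ages)
        idx = np.fromiter(w.gene_ids, int)
        log2_shift[idx] += shift[None, :]
    age_col = np.searchsorted(ages, cell_age)

    counts = np.empty((n_genes, n_cells), dtype=np.int64)

    # independent genes (everything not in a correlated module)
    correlated = module_ids.union(*background) if background else set(module_ids)
    indep = np.array(sorted(set(range(n_genes)) - correlated), dtype=int)
    mu_indep = (
        base_mu[indep, None]
        * 2.0 ** log2_shift[indep][:, age_col]
        * depth_factor[None, :]
    )
    size, p = _nb_size_p(mu_indep, spec.nb_dispersion)
    counts[indep] = rng.negative_binomial(size, p)

    # background programs: shared-factor copula at fixed rho, all cells
    for block, (size_b, rho) in zip(background, spec.background_modules):
        idx = np.array(block, int)
        mu_b = base_mu[idx, None] * 2.0 ** log2_shift[idx][:, age_col] * depth_factor[None, :]
        counts[idx] = _copula_nb(rng, mu_b, np.full_like(mu_b, spec.nb_dispersion), rho)

    # transition module: state-dependent rho and dispersion
    if transition:
        idx = np.array(sorted(module_ids), int)
        axis_vals = cell_age if transition.axis == "age" else meta["pseudotime"].to_numpy()
        in_state = transition.contains(axis_vals)
        mu_m = base_mu[idx, None] * 2.0 ** log2_shift[idx][:, age_col] * depth_factor[None, :]
        theta = np.full_like(mu_m, spec.nb_dispersion)
        theta[:, in_state] = _inflated_theta(
            mu_m[:, in_state], spec.nb_dispersion, transition.sd_inflation
        )
        out = np.zeros((len(idx), n_cells), dtype=np.int64)
        if in_state.any():
            out[:, in_state] = _copula_nb(
                rng, mu_m[:, in_state], theta[:, in_state], transition.rho_in_state
            )
        if (~in_state).any():
            out[:, ~in_state] = _copula_nb(
                rng, mu_m[:, ~in_state], theta[:, ~in_state], transition.rho_baseline
            )
        counts[idx] = out

    matrix = CountMatrix(
        values=sparse.csr_matrix(counts),
        gene_ids=_gene_names(n_genes, n_mito),
        cell_ids=meta["cell_id"].tolist(),
    )
    truth = PlantedTruth(
        wave_centers=tuple(w.center_age for w in waves),
        wave_gene_ids=tuple(tuple(sorted(w.gene_ids)) for w in waves),
        module_gene_ids=tuple(sorted(module_ids)),
        tipping_state=tuple(transition.state_interval) if transition else None,
        background_gene_ids=tuple(tuple(b) for b in background),
        seed=spec.seed,
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# mouse cohort


def generate_mouse_cohort(
    age_months: list[int],
    samples_per_age: int,
    n_genes: int,
    transition: TransitionSpec | None,
    seed: int,
    *,
    depth_scale: float = 50.0,
    nb_dispersion: float = 10.0,
    background_modules: tuple[tuple[int, float], ...] = ((20, 0.4), (20, 0.4), (20, 0.4)),
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Bulk RNA-seq cohort over a grid of mouse ages (months).

    Returns (samples × genes count DataFrame, sample metadata, truth).
    Bulk counts use a higher sequencing depth and a tighter dispersion than
    the single-nucleus generator, as replicate-level bulk data do.
    """
    months = np.asarray(age_months, float)
    if months.size == 0 or np.any(np.diff(months) <= 0):
        raise ValueError("age_months must be non-empty and strictly increasing")
    if samples_per_age < 1 or n_genes < 1:
        raise ValueError("samples_per_age and n_genes must be positive")
    module_ids: set[int] = set(transition.module_gene_ids) if transition else set()
    if transition:
        t_lo, t_hi = transition.state_interval
        if not ((months >= t_lo) & (months <= t_hi)).any():
            raise ValueError("transition interval contains no month on the grid")
        if max(module_ids) >= n_genes:
            raise ValueError("transition module gene ids out of range")

    rng = np.random.default_rng(seed)
    base_mu = rng.lognormal(np.log(depth_scale), 1.0, n_genes)

    sample_age = np.repeat(months, samples_per_age)
    n_samples = sample_age.size
    meta = pd.DataFrame(
        {
            "sample_id": [f"M{i:03d}" for i in range(n_samples)],
            "age_months": sample_age,
        }
    )

    background: list[list[int]] = []
    next_idx = n_genes
    for size_b, rho in background_modules:
        block = list(range(next_idx - size_b, next_idx))
        next_idx -= size_b
        if set(block) & module_ids:
            raise ValueError("background modules overlap the transition module")
        background.append(block)

    counts = np.empty((n_samples, n_genes), dtype=np.int64)
    correlated = module_ids.union(*background) if background else set(module_ids)
    indep = np.array(sorted(set(range(n_genes)) - correlated), dtype=int)
    mu = np.broadcast_to(base_mu[indep], (n_samples, indep.size))
    size, p = _nb_size_p(mu, nb_dispersion)
    counts[:, indep] = rng.negative_binomial(size, p)

    for block, (size_b, rho) in zip(background, background_modules):
        idx = np.array(block, int)
        mu_b = np.broadcast_to(base_mu[idx, None], (idx.size, n_samples))
        counts[:, idx] = _copula_nb(rng, mu_b, np.full_like(mu_b, float(nb_dispersion)), rho).T

    if transition:
        idx = np.array(sorted(module_ids), int)
        in_state = transition.contains(sample_age)
        mu_m = np.broadcast_to(base_mu[idx, None], (idx.size, n_samples)).copy()
        theta = np.full_like(mu_m, float(nb_dispersion))
        theta[:, in_state] = _inflated_theta(mu_m[:, in_state], nb_dispersion, transition.sd_inflation)
        block_counts = np.zeros((idx.size, n_samples), dtype=np.int64)
        block_counts[:, in_state] = _copula_nb(
            rng, mu_m[:, in_state], theta[:, in_state], transition.rho_in_state
        )
        block_counts[:, ~in_state] = _copula_nb(
            rng, mu_m[:, ~in_state], theta[:, ~in_state], transition.rho_baseline
        )
        counts[:, idx] = block_counts.T

    gene_names = _gene_names(n_genes, 0)
    matrix = pd.DataFrame(counts, index=meta["sample_id"], columns=gene_names)
    truth = PlantedTruth(
        wave_centers=(),
        wave_gene_ids=(),
        module_gene_ids=tuple(sorted(module_ids)),
        tipping_state=tuple(transition.state_interval) if transition else None,
        background_gene_ids=tuple(tuple(b) for b in background),
        seed=seed,
    )
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# on-disk layout: Matrix Market counts + genes.tsv + cells.tsv (+ truth.json)


def write_cohort(
    matrix: CountMatrix,
    meta: pd.DataFrame,
    path: str | Path,
    truth: PlantedTruth | None = None,
) -> None:
    """Write a cohort as matrix.mtx + genes.tsv + cells.tsv (+ truth.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cells metadata missing required columns: {missing}")
    if list(meta["cell_id"]) != list(matrix.cell_ids):
        raise ValueError("metadata cell_id order does not match the count matrix")
    mmwrite(path / "matrix.mtx", matrix.values.tocoo(), field="integer")
    genes = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "is_mito": [int(g.startswith("MT-")) for g in matrix.gene_ids],
        }
    )
    genes.to_csv(path / "genes.tsv", sep="\t", index=False)
    meta.to_csv(path / "cells.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_json(path / "truth.json")


def read_cohort(path: str | Path) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`; validates consistency."""
    path = Path(path)
    values = sparse.csr_matrix(mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "genes.tsv", sep="\t")
    meta = pd.read_csv(path / "cells.tsv", sep="\t")
    if "gene_id" not in genes.columns:
        raise ValueError("genes.tsv: missing required column gene_id")
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cells.tsv: missing required columns: {missing}")
    if len(genes) != values.shape[0]:
        raise ValueError(
            f"genes.tsv has {len(genes)} rows but matrix.mtx has {values.shape[0]} genes"
        )
    if len(meta) != values.shape[1]:
        raise ValueError(
            f"cells.tsv has {len(meta)} rows but matrix.mtx has {values.shape[1]} cells"
        )
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"cells.tsv: duplicated cell_id {dup!r}")
    matrix = CountMatrix(
        values=values,
        gene_ids=genes["gene_id"].tolist(),
        cell_ids=meta["cell_id"].tolist(),
    )
    return matrix, meta
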