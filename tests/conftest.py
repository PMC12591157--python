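import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import braintip as bt
from braintip.qc import filter_nuclei, normalize_log


SMALL_AGE_GRID = (42, 48, 54, 58, 60, 66, 72, 80)


def small_spec(seed: int = 0, **kw) -> bt.CohortSpec:
    defaults = dict(
        age_grid=SMALL_AGE_GRID,
        donors_per_age=2,
        cells_per_donor=40,
        n_genes=300,
        background_modules=((10, 0.4), (10, 0.4)),
        seed=seed,
    )
    defaults.update(kw)
    return bt.CohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A small null cohort (no waves, no transition) shared across tests."""
    spec = small_spec(seed=11)
    matrix, meta, truth = bt.generate_cohort(spec)
    return spec, matrix, meta, truth


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    _, matrix, meta, _ = small_cohort
    filtered, fmeta, _ = filter_nuclei(
        matrix, meta, bt.qc.QCConfig(min_features=1, max_features=10_000)
    )
    return normalize_log(filtered), fmeta


def nb_counts(rng, mu, theta, n_cells):
    """NB count matrix (genes x cells) at per-gene means mu, dispersion theta."""
    mu = np.asarray(mu, float)[:, None]
    theta = np.broadcast_to(np.asarray(theta, float)[..., None] if np.ndim(theta) else theta,
                            (mu.shape[0], 1))
    return rng.negative_binomial(theta, theta / (theta + mu), (mu.shape[0], n_cells))


def make_count_matrix(values, n_mito: int = 0) -> bt.CountMatrix:
    values = np.asarray(values)
    n_genes, n_cells = values.shape
    names = [("MT-" if i < n_mito else "") + f"G{i:04d}" for i in range(n_genes)]
    return bt.CountMatrix(
        values=sparse.csr_matrix(values),
        gene_ids=names,
        cell_ids=[f"C{i:05d}" for i in range(n_cells)],
    )


def make_meta(n_cells: int, **columns) -> pd.DataFrame:
    base = {
        "cell_id": [f"C{i:05d}" for i in range(n_cells)],
        "donor_id": ["D0"] * n_cells,
        "age": [50.0] * n_cells,
        "sex": ["F"] * n_cells,
        "region": ["cortex"] * n_cells,
        "cell_type": ["T"] * n_cells,
        "pseudotime": np.linspace(0, 1, n_cells),
    }
    base.update(columns)
    return pd.DataFrame(base)
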