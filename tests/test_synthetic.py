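"""Generator: determinism, planted structure, round-trip IO."""

import numpy as np
import pandas as pd
import pytest

import braintip as bt
from braintip.synthetic import DEFAULT_AGE_GRID
from conftest import SMALL_AGE_GRID, small_spec

from braintip._stats import rank_sum_test


def test_seeded_determinism():
    spec = small_spec(seed=7)
    waves = [bt.WaveSpec(center_age=60, gene_ids=frozenset(range(20, 50)))]
    m1, meta1, t1 = bt.generate_cohort(spec, waves)
    m2, meta2, t2 = bt.generate_cohort(spec, waves)
    assert (m1.values != m2.values).nnz == 0
    pd.testing.assert_frame_equal(meta1, meta2)
    assert t1 == t2


def test_default_cohort_dimensions():
    spec = bt.CohortSpec(seed=3)
    matrix, meta, _ = bt.generate_cohort(spec)
    assert matrix.values.shape == (2000, 29 * 200)
    assert len(meta) == 5800
    assert meta["donor_id"].nunique() == 29
    assert sorted(meta["age"].unique()) == sorted(float(a) for a in DEFAULT_AGE_GRID)
    # mito genes lead the gene list with the MT- prefix
    n_mito = spec.n_mito
    assert all(g.startswith("MT-") for g in matrix.gene_ids[:n_mito])
    assert not any(g.startswith("MT-") for g in matrix.gene_ids[n_mito:])


def test_wave_shifts_group_means_per_logistic_oracle():
    """Empirical old/young fold of wave genes matches the logistic mean law."""
    wave = bt.WaveSpec(center_age=60, gene_ids=frozenset(range(20, 80)),
                       log2_effect=1.0, steepness=0.5)
    spec = small_spec(seed=5, cells_per_donor=120, n_genes=400)
    matrix, meta, _ = bt.generate_cohort(spec, [wave])
    counts = matrix.values.toarray()
    idx = np.arange(20, 80)
    old = meta["age"].to_numpy() >= 70
    young = meta["age"].to_numpy() <= 50
    observed = counts[np.ix_(idx, np.flatnonzero(old))].mean() / \
        counts[np.ix_(idx, np.flatnonzero(young))].mean()
    # oracle: per-donor mean multiplier from the same logistic law
    ages = meta["age"].to_numpy()
    expected = np.mean(2.0 ** wave.log2_shift(ages[old])) / \
        np.mean(2.0 ** wave.log2_shift(ages[young]))
    assert observed == pytest.approx(expected, rel=0.1)
    assert expected == pytest.approx(2.0, rel=0.05)  # ~2-fold at these ages


def test_confounded_truth_rejected():
    waves = [bt.WaveSpec(center_age=60, gene_ids=frozenset(range(20, 40)))]
    transition = bt.TransitionSpec(state_interval=(56, 60),
                                   module_gene_ids=frozenset(range(30, 50)))
    with pytest.raises(ValueError, match="confounded"):
        bt.generate_cohort(small_spec(), waves, transition)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        bt.CohortSpec(age_grid=())
    with pytest.raises(ValueError):
        bt.CohortSpec(age_grid=(50, 40))
    with pytest.raises(ValueError):
        bt.WaveSpec(center_age=60, gene_ids=frozenset())
    with pytest.raises(ValueError):
        bt.TransitionSpec(state_interval=(56, 60), module_gene_ids=frozenset({1}),
                          rho_in_state=0.2, rho_baseline=0.4)
    with pytest.raises(ValueError, match="hull"):
        bt.generate_cohort(small_spec(),
                           [bt.WaveSpec(center_age=20, gene_ids=frozenset({5}))])


def test_null_cohort_rank_tests_calibrated():
    """With nothing planted, cell-level rank tests between age halves reject
    at ~ the nominal level (checked over the independent genes)."""
    spec = small_spec(seed=21, n_genes=1100, donors_per_age=1, cells_per_donor=30,
                      background_modules=())
    matrix, meta, _ = bt.generate_cohort(spec)
    x = matrix.values.toarray().astype(float)
    ages = meta["age"].to_numpy()
    split = np.median(ages)
    _, p = rank_sum_test(x[:, ages <= split].T, x[:, ages > split].T)
    rate = (p < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / spec.n_genes)
    assert abs(rate - 0.05) < 3 * se


def test_planted_module_correlation_margin():
    """Intra-module |r| inside the transition state exceeds outside by a
    margin reflecting rho_in_state - rho_baseline."""
    gaps = []
    for seed in range(3):
        spec = small_spec(seed=seed, cells_per_donor=80)
        transition = bt.TransitionSpec(state_interval=(56, 60),
                                       module_gene_ids=frozenset(range(100, 115)))
        matrix, meta, truth = bt.generate_cohort(spec, [], transition)
        x = matrix.values.toarray().astype(float)
        mod = np.array(truth.module_gene_ids)
        ages = meta["age"].to_numpy()

        def mean_abs_r(cells):
            r = np.corrcoef(x[np.ix_(mod, np.flatnonzero(cells))])
            return (np.abs(r).sum() - len(mod)) / (len(mod) * (len(mod) - 1))

        gaps.append(mean_abs_r((ages >= 56) & (ages <= 60)) -
                    mean_abs_r((ages < 56) | (ages > 60)))
    # latent gap is 0.5; the copula + counts attenuate it, but it stays large
    assert min(gaps) > 0.15


def test_mouse_cohort_dimensions_and_null_exchangeability():
    months = [3, 6, 9, 12, 15, 18, 21, 24, 28]
    mat, meta, _ = bt.generate_mouse_cohort(months, 6, 200, None, seed=2)
    assert mat.shape == (54, 200)
    assert (meta.groupby("age_months").size() == 6).all()
    # no transition: month-18 group SD comparable to the rest
    x = np.log1p(mat.to_numpy().astype(float))
    in18 = (meta["age_months"] == 18).to_numpy()
    ratio = x[in18].std(axis=0, ddof=1).mean() / x[~in18].std(axis=0, ddof=1).mean()
    assert ratio == pytest.approx(1.0, abs=0.1)


def test_mouse_planted_sd_inflation_ratio():
    """Module-gene count SD in the transition month is ~ sd_inflation times
    the SD elsewhere (averaged over seeds)."""
    months = [3, 6, 9, 12, 15, 18, 21, 24, 28]
    module = frozenset(range(50, 70))
    ratios = []
    for seed in range(20):
        transition = bt.TransitionSpec(state_interval=(18, 18), module_gene_ids=module,
                                       sd_inflation=3.0)
        mat, meta, _ = bt.generate_mouse_cohort(months, 6, 150, transition, seed=seed)
        x = mat.to_numpy().astype(float)
        mod = sorted(module)
        in18 = (meta["age_months"] == 18).to_numpy()
        ratios.append(
            x[np.ix_(in18, mod)].std(axis=0, ddof=1).mean()
            / x[np.ix_(~in18, mod)].std(axis=0, ddof=1).mean()
        )
    assert np.mean(ratios) == pytest.approx(3.0, rel=0.2)


def test_mouse_transition_off_grid_rejected():
    with pytest.raises(ValueError, match="no month"):
        bt.generate_mouse_cohort(
            [3, 6, 9], 4, 100,
            bt.TransitionSpec(state_interval=(18, 18), module_gene_ids=frozenset({1, 2})),
            seed=0,
        )


class TestCohortIO:
    def test_round_trip_lossless(self, tmp_path, small_cohort):
        _, matrix, meta, truth = small_cohort
        bt.write_cohort(matrix, meta, tmp_path / "cohort", truth)
        matrix2, meta2 = bt.read_cohort(tmp_path / "cohort")
        assert (matrix.values != matrix2.values).nnz == 0
        assert matrix.gene_ids == matrix2.gene_ids
        assert list(meta2["cell_id"]) == matrix.cell_ids
        assert bt.PlantedTruth.from_json(tmp_path / "cohort" / "truth.json") == truth

    def test_duplicated_cell_id_rejected(self, tmp_path, small_cohort):
        _, matrix, meta, _ = small_cohort
        bt.write_cohort(matrix, meta, tmp_path / "c")
        cells = pd.read_csv(tmp_path / "c" / "cells.tsv", sep="\t")
        cells.loc[1, "cell_id"] = cells.loc[0, "cell_id"]
        cells.to_csv(tmp_path / "c" / "cells.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicated cell_id"):
            bt.read_cohort(tmp_path / "c")

    def test_missing_metadata_column_rejected(self, tmp_path, small_cohort):
        _, matrix, meta, _ = small_cohort
        bt.write_cohort(matrix, meta, tmp_path / "c")
        cells = pd.read_csv(tmp_path / "c" / "cells.tsv", sep="\t").drop(columns=["age"])
        cells.to_csv(tmp_path / "c" / "cells.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="age"):
            bt.read_cohort(tmp_path / "c")

    def test_dimension_mismatch_names_file(self, tmp_path, small_cohort):
        _, matrix, meta, _ = small_cohort
        bt.write_cohort(matrix, meta, tmp_path / "c")
        genes = pd.read_csv(tmp_path / "c" / "genes.tsv", sep="\t").iloc[:-5]
        genes.to_csv(tmp_path / "c" / "genes.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="genes.tsv"):
            bt.read_cohort(tmp_path / "c")
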