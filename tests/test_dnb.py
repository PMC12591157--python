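"""DNB scoring: state binning, module detection, CI oracle, tipping point."""

import numpy as np
import pandas as pd
import pytest

import braintip as bt
from braintip import dnb
from braintip.qc import filter_nuclei, normalize_log
from conftest import make_meta, small_spec


def brute_force_ci(x, module_idx):
    """Independent CI oracle: explicit per-pair Pearson correlations."""
    x = np.asarray(x, float)
    module_idx = sorted(module_idx)
    outside = [i for i in range(x.shape[0]) if i not in set(module_idx)]

    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        return 0.0 if denom == 0 else float((a * b).sum() / denom)

    sd_in = np.mean([np.std(x[i], ddof=1) for i in module_idx])
    pairs_in = [
        abs(pearson(x[i], x[j]))
        for k, i in enumerate(module_idx)
        for j in module_idx[k + 1 :]
    ]
    pcc_in = float(np.mean(pairs_in))
    pcc_out = float(np.mean([abs(pearson(x[i], x[j])) for i in module_idx for j in outside]))
    return (pcc_in / max(pcc_out, 1e-6)) * sd_in, sd_in, pcc_in, pcc_out


class TestBinStates:
    def test_quantile_bins_equal_frequency(self):
        meta = make_meta(1000, pseudotime=np.random.default_rng(0).random(1000))
        states = dnb.bin_states(meta, mode="pseudotime", n_states=10)
        sizes = [len(s.cell_index) for s in states.states]
        assert sizes == [100] * 10

    @pytest.mark.parametrize(
        "age,state", [(58, "[56,60]"), (61, "[61,64]"), (29, "[29,41]"), (94, "[90,94]")]
    )
    def test_default_age_bins(self, age, state):
        meta = make_meta(1, age=[float(age)])
        states = dnb.bin_states(meta, mode="age")
        assert states.states[0].state_id == state

    def test_missing_axis_named_in_error(self):
        with pytest.raises(ValueError, match="pseudotime"):
            dnb.bin_states(make_meta(3).drop(columns=["pseudotime"]), mode="pseudotime")

    def test_states_partition_cells(self):
        rng = np.random.default_rng(1)
        meta = make_meta(200, age=rng.choice([30, 45, 58, 70, 92], 200).astype(float))
        states = dnb.bin_states(meta, mode="age")
        covered = sorted(i for s in states.states for i in s.cell_index)
        assert covered == list(range(200))


def _block_expr(rng, n_cells=250, rho=0.8, block=20, n_noise=60):
    """Two correlated blocks of `block` genes plus independent noise genes."""
    def draw(size):
        f = rng.standard_normal(n_cells)
        return np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal((size, n_cells))

    return np.vstack([draw(block), draw(block), rng.standard_normal((n_noise, n_cells))])


class TestClusterModules:
    def test_recovers_planted_blocks(self):
        for seed in range(3):
            x = _block_expr(np.random.default_rng(seed))
            modules = dnb.cluster_gene_modules(x, min_module_size=10, cut_height=0.75)
            assert len(modules) == 2
            found = {frozenset(m.gene_idx) for m in modules}
            assert found == {frozenset(range(20)), frozenset(range(20, 40))}

    def test_independent_genes_yield_no_modules(self):
        for seed in range(3):
            x = np.random.default_rng(100 + seed).standard_normal((80, 150))
            assert dnb.cluster_gene_modules(x, min_module_size=10) == []

    def test_zero_cut_yields_singletons(self):
        x = _block_expr(np.random.default_rng(5))
        assert dnb.cluster_gene_modules(x, min_module_size=2, cut_height=0.0) == []

    def test_requires_variable_genes(self):
        with pytest.raises(ValueError, match="variance"):
            dnb.cluster_gene_modules(np.ones((5, 10)))


class TestComputeCI:
    def test_closed_form_construction(self):
        """Two perfectly correlated module genes with |r|=0.5 to all outside
        genes: CI = (1/0.5) * sigma."""
        n = 16
        rng = np.random.default_rng(0)
        v = rng.standard_normal(n)
        v = (v - v.mean()) / v.std(ddof=1)  # sigma = 1
        u = rng.standard_normal(n)
        u -= u.mean() + v * (u @ v) / (v @ v)  # orthogonal to v, centered
        u /= u.std(ddof=1)
        w = 0.5 * v + np.sqrt(1 - 0.25) * u  # corr(v, w) = 0.5 exactly
        x = np.vstack([v, v, w, w, w])
        score = dnb.compute_ci(x, dnb.GeneModule((0, 1)))
        assert score.pcc_in == pytest.approx(1.0, abs=1e-12)
        assert score.pcc_out == pytest.approx(0.5, abs=1e-12)
        assert score.ci == pytest.approx(2.0, abs=1e-10)

    def test_scale_law_exact(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 50))
        module = dnb.GeneModule(tuple(range(8)))
        base = dnb.compute_ci(x, module)
        scaled = dnb.compute_ci(3.5 * x, module)
        assert scaled.ci == pytest.approx(3.5 * base.ci, rel=1e-12)
        assert scaled.pcc_in == pytest.approx(base.pcc_in, abs=1e-12)
        assert scaled.pcc_out == pytest.approx(base.pcc_out, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n_genes = int(rng.integers(12, 50))
            n_cells = int(rng.integers(20, 200))
            x = rng.standard_normal((n_genes, n_cells))
            module = tuple(sorted(rng.choice(n_genes, 10, replace=False).tolist()))
            score = dnb.compute_ci(x, dnb.GeneModule(module))
            ci, sd_in, pcc_in, pcc_out = brute_force_ci(x, module)
            assert score.ci == pytest.approx(ci, abs=1e-10)
            assert score.sd_in == pytest.approx(sd_in, abs=1e-12)
            assert score.pcc_in == pytest.approx(pcc_in, abs=1e-12)
            assert score.pcc_out == pytest.approx(pcc_out, abs=1e-12)

    def test_full_universe_module_rejected(self):
        x = np.random.default_rng(0).standard_normal((5, 20))
        with pytest.raises(ValueError, match="PCC_out"):
            dnb.compute_ci(x, dnb.GeneModule(tuple(range(5))))


@pytest.fixture(scope="module")
def planted_transition_run():
    spec = small_spec(seed=17, cells_per_donor=60, n_genes=500,
                      background_modules=((15, 0.4), (15, 0.4)))
    transition = bt.TransitionSpec(state_interval=(56, 60),
                                   module_gene_ids=frozenset(range(200, 220)))
    matrix, meta, truth = bt.generate_cohort(spec, [], transition)
    filtered, fmeta, _ = filter_nuclei(
        matrix, meta, bt.qc.QCConfig(min_features=1, max_features=10_000)
    )
    norm = normalize_log(filtered)
    states = dnb.bin_states(fmeta, mode="age")
    scores = dnb.score_states(norm, states)
    return truth, fmeta, states, scores, norm


class TestScoreStatesAndTipping:
    def test_planted_state_dominates(self, planted_transition_run):
        truth, _, _, scores, _ = planted_transition_run
        best = max(scores, key=lambda s: scores[s].ci)
        assert best == "[56,60]"
        others = [s.ci for sid, s in scores.items() if sid != best]
        assert scores[best].ci > max(others)

    def test_ablation_collapses_peak(self, planted_transition_run):
        truth, fmeta, states, scores, norm = planted_transition_run
        keep = np.setdiff1d(np.arange(norm.shape[0]), np.array(truth.module_gene_ids))
        ablated = dnb.score_states(norm.toarray()[keep], states)
        ratio_full = scores["[56,60]"].ci / np.median([s.ci for s in scores.values()])
        ratio_abl = ablated["[56,60]"].ci / np.median([s.ci for s in ablated.values()])
        assert ratio_abl < ratio_full * 0.7

    def test_tipping_report(self, planted_transition_run):
        truth, fmeta, states, scores, _ = planted_transition_run
        report = dnb.locate_tipping_point(scores, states, fmeta)
        assert report.tipping_state == "[56,60]"
        assert report.modal_age_bin == "[56,60]"
        assert set(report.dnb_genes) == set(truth.module_gene_ids)
        # labels partition the eligible cells
        counts = report.labels["label"].value_counts()
        assert counts.sum() == len(report.labels)
        assert {"young", "tipping", "old"} == set(counts.index)

    def test_monotone_ci_tips_at_boundary(self, planted_transition_run):
        _, fmeta, states, scores, _ = planted_transition_run
        forced = {
            sid: dnb.DNBScore(sid, s.module, s.sd_in, s.pcc_in, s.pcc_out, ci=float(i))
            for i, (sid, s) in enumerate(sorted(scores.items()))
        }
        report = dnb.locate_tipping_point(forced, states, fmeta)
        assert report.boundary_warning

    def test_too_few_states_rejected(self, planted_transition_run):
        _, fmeta, states, scores, _ = planted_transition_run
        two = {k: scores[k] for k in list(scores)[:2]}
        with pytest.raises(ValueError, match="3 scorable"):
            dnb.locate_tipping_point(two, states, fmeta)


class TestExportNetwork:
    def test_perfect_triangle(self):
        t = np.linspace(-1, 1, 10)
        x = np.vstack([t, 2 * t, -t, np.random.default_rng(0).standard_normal(10) * 1e-3])
        edges = dnb.export_network(x, dnb.GeneModule((0, 1, 2)), r_threshold=0.3)
        module_edges = edges[(edges.gene_a < 3) & (edges.gene_b < 3)]
        assert len(module_edges) == 3
        np.testing.assert_allclose(np.abs(module_edges["r"]), 1.0, atol=1e-12)

    def test_unsatisfiable_threshold_empty(self):
        x = np.random.default_rng(1).standard_normal((6, 20))
        edges = dnb.export_network(x, dnb.GeneModule((0, 1)), r_threshold=1.01)
        assert edges.empty

    def test_edge_count_matches_brute_force(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((15, 40))
        module = dnb.GeneModule((0, 1, 2, 3))
        thr = 0.3
        edges = dnb.export_network(x, module, r_threshold=thr)
        r = np.corrcoef(x)
        outside = [i for i in range(15) if i > 3]
        nodes = set(module.gene_idx) | {
            i for i in outside if np.abs(r[i, list(module.gene_idx)]).mean() > thr
        }
        expected = sum(
            1
            for a in sorted(nodes)
            for b in sorted(nodes)
            if a < b and abs(r[a, b]) >= thr
        )
        assert len(edges) == expected
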