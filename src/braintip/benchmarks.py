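"""End-to-end planted-truth benchmarks at the study's cohort conditions.

Each function generates a seeded synthetic cohort, runs the relevant
pipeline stages from scratch, and returns the measured quantity. They are
used both by the acceptance script and by the test suite.
"""

from __future__ import annotations

import numpy as np

from . import deswan, dnb, qc, synthetic

# Ages at which molecular dysregulation waves are planted / probed; the
# earliest one is the canonical wave benchmark center.
WAVE_AGES = (60, 70, 79)
TIPPING_BIN = (56, 60)  # human tipping-point age bin
MOUSE_MONTHS = (3, 6, 9, 12, 15, 18, 21, 24, 28)
MOUSE_TIPPING_MONTH = 18

# bulk-mode DNB operating point (see methods note): at ~6 replicates the
# null |r| level is ~0.4, so module detection runs on the top-SD genes with
# a tighter tree cut than the single-cell default
MOUSE_CUT_HEIGHT = 0.4
MOUSE_TOP_SD_GENES = 100


def _prepare_cohort(spec, waves=None, transition=None):
    matrix, meta, truth = synthetic.generate_cohort(spec, waves, transition)
    cfg = qc.QCConfig()
    filtered, fmeta, _ = qc.filter_nuclei(matrix, meta, cfg)
    fmeta = qc.assign_age_groups(fmeta)
    norm = qc.normalize_log(filtered, cfg)
    return filtered, fmeta, norm, truth


def deswan_wave_benchmark(seed: int, center_age: float = WAVE_AGES[0]):
    """Plant a 300-gene sigmoidal up-wave at ``center_age`` in the default
    29-age cohort and scan for the profile peak.

    Returns (age of the highest profile peak, profile table).
    """
    spec = synthetic.CohortSpec(seed=seed)
    wave = synthetic.WaveSpec(
        center_age=center_age,
        gene_ids=frozenset(range(spec.n_mito, spec.n_mito + 300)),
        log2_effect=1.0,
        steepness=0.5,
        direction="up",
    )
    _, fmeta, norm, _ = _prepare_cohort(spec, [wave])
    unit, donor_meta = deswan.pseudobulk(norm, fmeta)
    profile = deswan.deswan_profile(unit, donor_meta["age"], deswan.SwanConfig())
    peaks = deswan.find_peaks(profile)
    return peaks[0][0], profile


def deswan_null_benchmark(seeds) -> float:
    """Mean fraction of genes significant at raw p < alpha per non-skipped
    window center, on cohorts with nothing planted."""
    fractions = []
    for seed in seeds:
        spec = synthetic.CohortSpec(seed=seed)
        _, fmeta, norm, _ = _prepare_cohort(spec)
        unit, donor_meta = deswan.pseudobulk(norm, fmeta)
        profile = deswan.deswan_profile(unit, donor_meta["age"], deswan.SwanConfig())
        active = profile.loc[~profile["skipped"]]
        fractions.append(float((active["n_significant_p"] / spec.n_genes).mean()))
    return float(np.mean(fractions))


def human_tipping_benchmark(seed: int):
    """Plant a 20-gene transition module in the tipping age bin and locate
    the tipping state by age-binned DNB scoring.

    Returns the TippingReport.
    """
    spec = synthetic.CohortSpec(seed=seed)
    transition = synthetic.TransitionSpec(
        state_interval=TIPPING_BIN,
        module_gene_ids=frozenset(range(500, 520)),
        sd_inflation=3.0,
        rho_in_state=0.7,
        rho_baseline=0.2,
    )
    _, fmeta, norm, _ = _prepare_cohort(spec, None, transition)
    states = dnb.bin_states(fmeta, mode="age")
    scores = dnb.score_states(norm, states)
    return dnb.locate_tipping_point(scores, states, fmeta)


def mouse_tipping_benchmark(seed: int) -> float:
    """Plant a transition module in the month-18 group of a bulk mouse
    cohort and return the month whose dominant CI is maximal."""
    transition = synthetic.TransitionSpec(
        state_interval=(MOUSE_TIPPING_MONTH, MOUSE_TIPPING_MONTH),
        module_gene_ids=frozenset(range(500, 520)),
        sd_inflation=3.0,
        rho_in_state=0.7,
        rho_baseline=0.2,
    )
    matrix, meta, _ = synthetic.generate_mouse_cohort(
        list(MOUSE_MONTHS), 6, 2000, transition, seed
    )
    x = matrix.to_numpy().T.astype(float)
    x = np.log1p(x / x.sum(axis=0) * 1e4)
    ages = meta["age_months"].to_numpy()
    states = dnb.StateClustering(
        states=[
            dnb.State(f"m{m:g}", i, (float(m), float(m)),
                      tuple(np.flatnonzero(ages == m)))
            for i, m in enumerate(MOUSE_MONTHS)
        ],
        mode="age",
    )
    scores = dnb.score_states(
        x, states,
        min_state_cells=4,
        cut_height=MOUSE_CUT_HEIGHT,
        top_sd_genes=MOUSE_TOP_SD_GENES,
    )
    best = max(scores, key=lambda sid: scores[sid].ci)
    return float(best[1:])
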