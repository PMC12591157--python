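"""Simulate the synthetic aging-brain cohort used by all downstream steps.

One human single-nucleus cohort on the 29-age grid (29-94 y, 1 donor/age,
200 cells/donor, 2000 genes) with the full planted structure:

* three sigmoidal dysregulation waves centred at ages 60, 70 and 79
  (150 genes each, log2 effect 1, slope 0.5/y);
* one critical-transition module (20 genes) in the 56-60 age bin
  (SD x3, intra-module correlation 0.7 vs 0.2 baseline).

Writes scratch/cohort/ (matrix.mtx + genes.tsv + cells.tsv + truth.json).
"""

from pathlib import Path

import braintip as bt

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

spec = bt.CohortSpec(seed=1)
waves = [
    bt.WaveSpec(center_age=c, gene_ids=frozenset(range(start, start + 150)))
    for c, start in [(60, 20), (70, 170), (79, 320)]
]
transition = bt.TransitionSpec(
    state_interval=(56, 60), module_gene_ids=frozenset(range(500, 520))
)

matrix, meta, truth = bt.generate_cohort(spec, waves, transition)
bt.write_cohort(matrix, meta, SCRATCH / "cohort", truth)

print(f"cohort: {matrix.n_genes} genes x {matrix.n_cells} cells, "
      f"{meta['donor_id'].nunique()} donors aged "
      f"{meta['age'].min():.0f}-{meta['age'].max():.0f}")
print(f"planted waves at {truth.wave_centers}, transition in {truth.tipping_state}")
print(f"written to {SCRATCH / 'cohort'}")
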