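"""Old-vs-young Wilcoxon differential expression (Padj < 0.05, FC > 1.2)
overall and per region, plus the between-region DEG overlap."""

import json
from pathlib import Path

import numpy as np

import braintip as bt
from braintip.diffexp import overlap_fraction, rank_sum_de
from braintip.qc import normalize_log

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"

matrix, meta = bt.read_cohort(SCRATCH / "cohort_qc")
norm = normalize_log(matrix)
labels = np.where(meta["age_group"] == "old", "A",
                  np.where(meta["age_group"] == "young", "B", "-"))

tables = {}
for name, mask in [
    ("all", labels != "-"),
    ("cortex", (labels != "-") & (meta["region"] == "cortex").to_numpy()),
    ("hippocampus", (labels != "-") & (meta["region"] == "hippocampus").to_numpy()),
]:
    idx = np.flatnonzero(mask)
    tables[name] = rank_sum_de(norm[:, idx], labels[idx], fc_threshold=1.2,
                               gene_ids=matrix.gene_ids)
    tables[name].to_csv(SCRATCH / f"de_old_vs_young_{name}.tsv", sep="\t")
    n_up = (tables[name]["direction"] == "up").sum()
    n_down = (tables[name]["direction"] == "down").sum()
    print(f"{name:12s}: {n_up} up / {n_down} down in the old group")

overlap = overlap_fraction(tables["cortex"], tables["hippocampus"])
with open(OUT / "deg_region_overlap.json", "w") as fh:
    json.dump(overlap, fh, indent=1)
print("cortex/hippocampus DEG overlap (Jaccard):",
      {k: (None if v is None else round(v, 2)) for k, v in overlap.items()})
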