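"""Filter nuclei (features in [500, 7500], mito fraction <= 5%), assign the
young (29-60) / old (65-94) groups, and store the QC report."""

from pathlib import Path

import braintip as bt
from braintip.qc import QCConfig, assign_age_groups, filter_nuclei

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"

matrix, meta = bt.read_cohort(SCRATCH / "cohort")
filtered, fmeta, report = filter_nuclei(matrix, meta, QCConfig())
fmeta = assign_age_groups(fmeta)
report.to_json(OUT / "qc_report.json")
bt.write_cohort(filtered, fmeta, SCRATCH / "cohort_qc")

kept = report.output_cells / report.input_cells
print(f"QC: {report.input_cells} -> {report.output_cells} nuclei ({kept:.1%} kept); "
      f"removed {report.removed_low_features} low-feature, "
      f"{report.removed_high_features} high-feature, "
      f"{report.removed_mito} high-mito")
print(fmeta["age_group"].value_counts().to_string())
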