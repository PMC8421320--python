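"""Run the full synthetic study and summarise PET-vs-MRI agreement.

Simulates a 12-subject rest/stress cohort, fits PET and the three MRI
routes at the global level, calibrates the population PS from plain-K1 vs
PET-MBF pairs, and prints cohort means, Bland-Altman agreement and the
flow-reserve correlation.
"""

import json
from pathlib import Path

from dualflow import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort=CohortConfig(n_subjects=12, seed=2026,
                        segment_heterogeneity_cv=0.0),
    regions="global", save_curves=False)
outdir = run_pipeline(config, Path("scratch") / "cohort_agreement")

print((outdir / "report.md").read_text())
summary = json.loads((outdir / "agreement.json").read_text())
mfr = summary["agreement"]["1tcm_ps"]["global_mfr"]
print(f"Flow reserve (1TCM+PS vs PET): Spearman r = {mfr['spearman_r']:.2f}, "
      f"bias = {mfr['bias']:.2f}")
print("\nBias near zero with moderate limits of agreement for the direct "
      "PS route; the\nflow-reserve correlation is weaker than the MBF "
      "correlation because the stress/rest\nratio compounds the errors of "
      "both measurements.")
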