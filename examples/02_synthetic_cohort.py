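"""Generate a ground-truthed synthetic study cohort and recover its rhythms.

Simulates 42 patients (2:1 treated:placebo) across six treatment stages with
a treated-arm phase advance and amplitude damping of the core clock genes,
then refits every series and compares the recovered acrophases between arms.
"""

import pandas as pd

from chronotox import CohortDesign, generate_cohort
from chronotox.pipeline import fit_cosinor_table

design = CohortDesign(n_patients=42, seed=1)
bundle = generate_cohort(design)
print(f"time-course rows: {len(bundle.timecourse)}, "
      f"PRO rows: {len(bundle.pro)}")

fits = fit_cosinor_table(bundle.timecourse)
w4 = fits[(fits["stage"] == "W4") & (fits["gene"] == "BMAL1")]
summary = w4.groupby("arm")["acrophase_h"].agg(["mean", "std", "count"])
print(summary.round(2))
# The treated arm's BMAL1 acrophase sits ~4 h earlier than placebo at week 4,
# reflecting the configured arm effect; the ground truth used for every
# sample is returned in bundle.ground_truth for direct comparison.
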