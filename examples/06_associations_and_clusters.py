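"""Clock-outcome association statistics and patient stratification.

Runs the full default pipeline on a simulated cohort: bootstrap OLS (and
Spearman with permutation p-values) of patient-reported outcomes on clock
covariates per arm, then k-means stratification on BMAL1 phase/expression
with silhouette-based model selection.
"""

import pandas as pd

from chronotox import RunConfig, run_pipeline

config = RunConfig(
    seed=1,
    n_patients=15,
    ols_n_boot=5000,          # 25,000 in full analyses
    spearman_n_boot=1000,
    spearman_n_perm=2000,
    out_dir="scratch/example_run",
)
report = run_pipeline(config)

assoc = pd.read_csv("scratch/example_run/associations.csv")
top = assoc.sort_values("p_boot").head(5)
cols = ["arm", "outcome", "covariate", "beta", "p_boot", "spearman_rho"]
print(top[cols].round(3).to_string(index=False))

clusters = report["stages"]["clusters"]
print(f"\nbest k = {clusters['k']} "
      f"(mean silhouette {clusters['silhouette_mean']:.2f})")
print(f"cluster-arm purity {clusters['arm_purity']:.2f}, "
      f"Fisher exact p = {clusters['arm_fisher_p']:.4f}")
# Couplings between clock phase and outcomes have opposite signs in the two
# arms by construction, and the treated arm's phase advance separates the
# arms in clock-feature space, which the clustering recovers.
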