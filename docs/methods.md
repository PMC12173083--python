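# Methods

This note documents the models, estimators and numerical choices behind
`chronotox`, in the order the pipeline runs them.

## Cosinor rhythmometry

A series of expression values y(tᵢ) at clock times tᵢ is modelled as
y = M + a·cos(ωt) + b·sin(ωt) + ε with fixed ω = 2π/24 h⁻¹ and Gaussian ε.
Because the period is fixed, the model is linear and solved in closed form
by least squares (no iteration). Derived quantities: amplitude
A = √(a² + b²); acrophase φ = (24/2π)·atan2(b, a) mod 24, the clock time of
peak expression. Two-day kits are pooled into one cycle through the periodic
basis — the fit sees only the phase angle 2π(t mod 24)/24, so day-2 samples
reinforce day-1 phases. The zero-amplitude ("rhythmicity") test is the
F-test of the two harmonic terms against the intercept-only model, the
standard single-component cosinor test; a constant series is reported with
p = 1.

Numerical conventions:

* **Degenerate amplitude.** If A < 10⁻⁹·|M| (absolute 10⁻¹² when M = 0) the
  acrophase is reported as undefined (`None`) rather than a number.
* **Degenerate design.** Samples covering fewer than two distinct phase
  angles leave the basis rank-deficient and raise an explicit error;
  fewer than 3 points raise an insufficient-data error. Fits on 3–4 points
  are flagged low-confidence.
* **Phase wrapping.** atan2 output is wrapped into [0, 24); a floating-point
  result that rounds to exactly 24 maps to 0.

ΔCt preprocessing follows the usual relative-quantification conventions:
ΔCt = Ct_target − Ct_reference, ΔΔCt relative to a calibrator,
fold change 2^−ΔΔCt; time-courses are additionally divided by their own mean
("mean normalisation"), so fitted MESORs sit near 1. Acrophase histograms
use fixed-width bins on [0, 24) (width must divide 24); binning is linear,
not circular, and undefined acrophases are counted separately.

## Panel normalisation

Raw lane × probe counts carry three technical effects that are removed in a
fixed order (the order is contractual and regression-tested):

1. **Positive-control scaling** — lane factor = (across-lane mean of
   per-lane positive-control means) / (lane mean); all counts in the lane
   are multiplied by it. Lanes with a zero positive mean are flagged and
   left unscaled.
2. **Background subtraction** — the lane's negative-control arithmetic mean
   is subtracted from every non-negative-control probe, floored at 1 (the
   floor keeps the subsequent log2 defined; its exact value is a package
   choice).
3. **Housekeeping normalisation** — lane factor = (across-lane mean of
   per-lane housekeeping geometric means) / (lane geometric mean), applied
   to housekeeping and endogenous probes. Afterwards every usable lane's
   housekeeping geometric mean equals the shared reference to ~1e−9
   relative.

The across-lane arithmetic mean is used as the global reference in both
scaling steps, and the factors are recorded in the output metadata. A
per-batch mean-centring of log2 endogenous values is available but off by
default and flagged experimental — the appropriate batch model is
study-specific. Note the absolute output level depends on all lanes through
the references; only relative structure is identifiable, which is what the
log2 differential analysis consumes.

## Differential expression and differential rhythmicity

Differential expression compares two groups of log2 values per gene with a
two-sample t statistic — pooled variance by default, Welch by flag — plus
Benjamini–Hochberg adjustment across genes. Significance uses the dual rule
nominal p < 0.05 AND |logFC| ≥ 0.2 (both cutoffs configurable). No
empirical-Bayes variance moderation is applied: with the small per-group
sample sizes this package targets, the plain t-test is the transparent
choice, and a moderated variant is an explicit extension point. Genes with
zero variance in both groups get p = 1 at equal means.

Differential rhythmicity fits the pooled two-condition harmonic model with
condition main effect and condition × (cos, sin) interactions and tests the
two interaction terms jointly by an F-test. Condition-specific amplitude
and acrophase come from the coefficient sums (a, b) and (a + Δa, b + Δb).
A gene is *flagged* when interaction p < 0.05 AND (circular phase shift
≥ 4 h OR relative amplitude change ≥ 50 %). The phase shift is the minimal
circular difference (23 h vs 1 h is 2 h, not 22). The amplitude criterion
|ΔA|/max(A₁, A₂) ≥ 0.5 is a package default — no numeric threshold is
standard — and is recorded in every result so analyses are self-describing.
At the 8-point two-day design the test's empirical size at α = 0.05 is
within [0.03, 0.07] and a planted 6-h shift at noise-to-amplitude 0.15 is
flagged in well over 80 % of simulations (both checked in the test suite).

## Clock/PK-PD model

The core clock is a compact transcription–translation feedback loop in six
states: Bmal1 and Per2 mRNAs (m_B, m_P), activator protein (CLOCK/BMAL1) in
cytoplasm and nucleus (c_A, n_A), repressor protein (PER/CRY) in cytoplasm
and nucleus (c_R, n_R). Transcription responses are Hill-type with exponent
h: Bmal1 is driven by a saturating *decreasing* function of n_A (fold range
a, scale kt1) and repressed by n_R (scale ki1); Per2 is activated by n_A
(fold i, scale kt5) and repressed by n_R (scale ki5). Translation (kiz6,
kiz7), nuclear import/export (kiz9/kex1, kiz4/kex2) and first-order
degradation (dy1, dy5; dx1, dx2, dx5, dx6) close the loop. The dominant
negative feedback runs n_R ⊣ Bmal1 → n_A → Per2 → n_R: a six-stage loop
that oscillates at moderate Hill exponents and automatically places the two
mRNAs near antiphase, matching BMAL1/PER2 biology. The drug arm is
D_ext → D_int → D_act (rates k_import, k_act, clearance k_clear), a damage
state dDAM/dt = k_damage·D_act − r(t)·DAM with circadian-gated repair
r(t) = r₀(1 + ρ·cos(2π(t − φ_PROTEIN)/24)), and a cumulative apoptosis
output dAPO/dt = k₀(1 + α·cos(2π(t − φ_apop)/24))·DAM. Gate depths ρ, α lie
in [0, 1], so both rates stay non-negative and APO is non-decreasing.

**Calibration instead of assertion.** The published values of the model
this surrogate abstracts are not reproduced here; instead
`calibrate_defaults` searches randomly (multiplicative perturbations within
±0.4 decades of a built-in guess) for parameter sets that oscillate with
the mRNA phase gap inside [8, 16] h, locally refines the best candidate by
a balance score (relative amplitudes in a usable range, state means near
1), and finally rescales all rate constants jointly so the free-running
period is *exactly* 24 h — a joint rescale of every rate rescales time
exactly, which the tests verify. The shipped default set records its
calibration seed and metrics (period 24.000 h, BMAL1 relative amplitude
0.89, phase gap 11.45 h). Integration uses LSODA with rtol 1e−8/atol 1e−10;
trajectories are checked for negative excursions beyond integrator
tolerance and tiny negatives are clipped.

**Personalisation.** The freed subset is exactly the 20 parameters
governing Bmal1/Per2 expression and their proteins: dy1, dy5, a, i, V1max,
V5max, kt1, ki1, kt5, ki5, dx1, dx2, dx5, dx6, kiz9, kex1, kiz4, kex2,
kiz6, kiz7. A (μ+λ) evolutionary strategy (defaults μ = 10, λ = 30, ≤ 200
generations, log-normal multiplicative mutation with σ = 0.15 on a random
~35 % of parameters, hard bounds [0.1×, 10×] the reference, early stop at
RMSE 1e−4 or 40 stalled generations, fully seeded) minimises the RMSE
between mean-normalised simulated m_B/m_P — burn-in 10 periods, sampled at
the patient's measurement clock times — and the mean-normalised measured
values, both genes weighted equally. The initial population contains the
reference set and time-rescaled variants of it (periods 23.4–24.6 h):
slightly detuned periods accumulate phase across the burn-in, giving the
search a direct, smooth handle on circadian phase. Model time 0 is anchored
to a 07:00 wake time; the fitted BMAL1 acrophase (cosinor over the 48-h
sampling window) minus the reference acrophase is the patient's phase
shift, applied modulo 24 to φ_PROTEIN and φ_apop ("gate alignment").

**Toxicity profiles.** After a drug-free burn-in (≥ 10 periods) the dose is
applied to D_ext at each of 24 hourly clock start times and integrated for
48 h; toxicity(t₀) = APO(t₀ + 48) − APO(t₀). A twice-daily option repeats
the bolus every 12 h. Summaries: average toxicity, absolute amplitude
(max − min)/2, relative amplitude, and the grid argmin/argmax as the
recommended/worst intake times. With gate depths 0 the curve is flat to
integrator precision; jointly shifting both gates translates the curve
without changing its average (both properties are tested).

## Resampling statistics

* **Spearman**: average-rank ρ; percentile CI from B = 2000 paired
  case-resamples (degenerate constant resamples dropped); permutation
  p = (1 + #{|ρ*| ≥ |ρ|})/(1 + P) with P = 10000 — add-one smoothing keeps
  p > 0.
* **Bootstrap OLS**: point estimates from the normal equations;
  case-resampling with B = 25000 by default; 95 % CI from the 2.5th/97.5th
  percentiles; two-tailed bootstrap p = 2·min(share ≤ 0, share ≥ 0) with
  add-one smoothing (floor 2/(B+1)). Diagnostics (Shapiro–Wilk on
  residuals, VIF, residual-vs-fitted correlation, adjusted R²) ride along
  as metadata. Resampled fits are solved in vectorised batches.
* **Standardized slope**: both variables z-scored with the population (n)
  denominator; the slope equals Pearson r, with the classical OLS CI.
* **Hedges' g**: d from the (n−1)-pooled SD, small-sample correction
  J = 1 − 3/(4(n₁+n₂) − 9), g = J·d, CI from the standard large-sample
  variance of g.
* **Basic tests**: Wilcoxon rank-sum (exact for tie-free samples ≤ 25 per
  group, normal approximation with tie correction otherwise), Fisher exact
  (hypergeometric for 2×2; exhaustive enumeration over tables with fixed
  margins for 2×k — feasible at cohort scale), two-sample
  Kolmogorov–Smirnov. BH adjustment is applied within explicitly declared
  test families, never silently pooled.
* Patient-level aggregation of repeated kits uses the mean (configurable);
  the study protocol does not prescribe one.

## Stratification

Clock features (e.g. BMAL1 acrophase and expression, PER2 MESOR) are
z-scored per column; k-means (k-means++ seeding, 50 restarts) runs for
k = 2…6 and the k with the highest mean silhouette is selected; the per-k
table is part of the result. Constant features are dropped with a warning;
an all-identical cohort returns a degenerate-flagged result rather than a
silhouette. Cluster–arm correspondence is summarised by a contingency
table, Fisher exact p and purity (share of patients whose cluster majority
matches their arm).

## Synthetic cohort generator

The generator emulates the study design so that every estimator can be
tested for recovery against known truth:

* **Design**: 42 patients, 2:1 treated:placebo, stages baseline/W4/W12/M6/
  M12/EOT, sampling at absolute hours 9, 13, 17, 21, 33, 37, 41, 45 with
  Gaussian jitter (sd 0.25 h, truncated at ±1 h — sampling times are only
  nominal in practice), optional per-stage dropout (default 0, recorded in
  the ground truth).
* **Expression**: value = mesor + amplitude·cos(2π(t − acrophase)/24) +
  Gaussian noise on the mean-normalised relative-expression scale
  (log-normal multiplicative noise available for count-like genes).
  Defaults: BMAL1 (M 1.0, A 0.4, φ 16 h), PER2 (1.0, 0.35, 5 h), PARP1
  (1.0, 0.2, 12 h), noise sd 0.1 — amplitudes and noise of this order are
  typical of mean-normalised saliva qPCR profiles; no published per-gene
  noise magnitudes exist for this assay, so these are calibration choices.
  Between-patient variability: acrophase sd 1 h, MESOR sd 0.05, log-normal
  amplitude factor (sd 0.15), constant within a patient.
* **Arm effects** apply only at post-baseline stages of the treated arm:
  additive acrophase and MESOR shifts, multiplicative amplitude scaling,
  per gene and optionally per stage. Defaults: BMAL1 −4 h phase advance
  with 0.7× amplitude, PER2 −3 h with 0.8×. The placebo arm receives zero
  effects (placebo drift exists in real data but is unquantified; the null
  default keeps the ground truth interpretable).
* **Outcomes**: score = intercept + Σ β_arm,cov·covariate + Gaussian noise,
  covariates being the patient's true stage-level rhythm parameters;
  default couplings put opposite signs on the two arms (e.g. nausea rises
  with BMAL1 phase advance under treatment). Step counts: monthly means,
  baseline 7000 minus 400 per adverse-event-score point, sd 500 — month-
  level pairing mirrors how tracker and questionnaire data align.
* **Bimodal cohorts**: a configurable fraction of treated patients gets an
  additional constant phase advance, producing the advanced/unchanged
  subgroup structure seen in treated cohorts.
* **Panel counts**: expected count = positive-scale × housekeeping-factor ×
  2^(true log2 abundance) + background, rounded (or Poisson-sampled);
  positive controls follow a fixed ladder scaled per lane; negatives carry
  background only. All factors are returned as ground truth.

Everything is driven by one `numpy` Generator seeded from the design, so
identical seeds give byte-identical tables. What the generator does *not*
emulate: assay chemistry and optics, item-level questionnaire responses,
informative missingness, placebo-arm drift, or non-sinusoidal waveforms —
recovery results on synthetic data therefore demonstrate estimator
correctness under the stated generative model, not robustness to every
real-data pathology.

## Pipeline and reproducibility

`run_pipeline` executes the enabled stages in dependency order; each
stochastic stage derives its seed from the run seed by hashing the stage
name, the report records the configuration hash, and identical
configurations reproduce identical reports (timing fields aside). Input
tables are schema-validated (required columns, numeric ranges, duplicated
sampling rows). Problem sizes in the shipped tests and the acceptance
script (cohorts of 10–42 patients, 100–1000 simulation replicates,
B = 2000 inside coverage loops with the 25,000 default elsewhere, EA
budgets of ~40 generations) were chosen to exercise every property at
study-realistic scale while keeping a full run in the minutes range on a
single core.

## Known limitations

* The ODE surrogate matches the *interface and contracts* of the published
  clock/PK-PD model family (parameter names, freed subset, gate phases,
  AUC toxicity read-out), not its numeric trajectories; no claim of
  equivalence to any published parameterisation is made.
* The evolutionary fit recovers circadian phase robustly but individual
  parameter values are not identifiable from 8 samples of 2 genes — only
  the fitted phase (and the resulting toxicity-curve timing) should be
  interpreted.
* The plain t-test is anti-conservative relative to moderated variants at
  very small n; the dual significance rule partly compensates.
* Fisher's exact 2×k enumeration is exponential in k and intended for
  cohort-scale tables only.
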