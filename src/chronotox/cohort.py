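"""Synthetic study-cohort generator with known ground truth.

Emulates the design of a placebo-controlled maintenance-therapy sub-study in
which sparse saliva time-courses (8 samples over two consecutive days at
roughly 9, 13, 17 and 21 h) are collected per patient at successive treatment
stages (baseline, weeks 4/12, months 6/12, end of treatment), with a 2:1
treated:placebo allocation.  Gene expression follows a 24-h cosinor curve per
patient x stage x gene; treated-arm patients receive configurable phase,
amplitude and MESOR effects at post-baseline stages.  Patient-reported
outcomes are linearly coupled to clock covariates with arm-specific signs,
and monthly step counts decrease with adverse-event burden.

Every generated artefact is a deterministic function of the design seed, and
the full generative ground truth is returned alongside the data so that each
downstream estimator can be tested for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelCountMatrix

__all__ = [
    "CohortDesign",
    "GeneRhythm",
    "ArmEffect",
    "ClockGroundTruth",
    "PROGroundTruth",
    "StepsGroundTruth",
    "PanelLaneTruth",
    "CohortBundle",
    "generate_cohort",
    "generate_bimodal_phase_cohort",
    "generate_panel_counts",
    "default_clock_truth",
    "default_pro_truth",
]

DEFAULT_STAGES = ("baseline", "W4", "W12", "M6", "M12", "EOT")
#: two-day kit: absolute hours 9/13/17/21 on day 1 and the same clock times on day 2
DEFAULT_SAMPLE_TIMES = (9.0, 13.0, 17.0, 21.0, 33.0, 37.0, 41.0, 45.0)


@dataclass
class CohortDesign:
    """Sampling design of the synthetic study."""

    n_patients: int = 42
    arm_ratio: tuple[int, int] = (2, 1)  # rucaparib : placebo
    stages: tuple[str, ...] = DEFAULT_STAGES
    sample_times_h: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    time_jitter_sd_h: float = 0.25  # 'ca. 9 h' etc.; truncated at +/- 1 h
    dropout_prob: float = 0.0  # per post-baseline stage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if min(self.arm_ratio) < 1:
            raise ValueError("arm ratio entries must be positive")
        times = np.asarray(self.sample_times_h, float)
        if np.any(np.diff(times) <= 0) or times[-1] > 48 or times[0] < 0:
            raise ValueError(
                "sample_times_h must be strictly increasing within [0, 48]"
            )
        if self.time_jitter_sd_h < 0:
            raise ValueError("time jitter sd must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")

    @property
    def arm_counts(self) -> tuple[int, int]:
        """(treated, placebo) patient counts implied by the ratio."""
        r1, r2 = self.arm_ratio
        n_treated = round(self.n_patients * r1 / (r1 + r2))
        return n_treated, self.n_patients - n_treated


@dataclass
class GeneRhythm:
    """Baseline cosinor parameters of one gene (relative-expression scale)."""

    mesor: float
    amplitude: float
    acrophase_h: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.acrophase_h < 24:
            raise ValueError("acrophase must lie in [0, 24)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class ArmEffect:
    """Treatment effect on rhythm parameters at post-baseline stages."""

    delta_acrophase_h: float = 0.0
    amplitude_scale: float = 1.0
    delta_mesor: float = 0.0

    def is_null(self) -> bool:
        return (
            self.delta_acrophase_h == 0.0
            and self.amplitude_scale == 1.0
            and self.delta_mesor == 0.0
        )


@dataclass
class ClockGroundTruth:
    """Generative counterpart of the cosinor model.

    ``genes`` holds baseline parameters; ``arm_effects`` maps gene ->
    (stage -> effect) applied in the treated arm at post-baseline stages
    (a plain :class:`ArmEffect` applies to every post-baseline stage).
    Between-patient variability adds Gaussian jitter to acrophase and MESOR
    and a log-normal factor to amplitude, constant within a patient.
    """

    genes: dict[str, GeneRhythm] = field(default_factory=dict)
    arm_effects: dict = field(default_factory=dict)
    patient_acrophase_sd_h: float = 1.0
    patient_mesor_sd: float = 0.05
    patient_amplitude_rel_sd: float = 0.15
    noise_model: str = "gaussian"  # or "lognormal"

    def effect_for(self, gene: str, stage: str) -> ArmEffect:
        eff = self.arm_effects.get(gene)
        if eff is None:
            return ArmEffect()
        if isinstance(eff, ArmEffect):
            return eff
        return eff.get(stage, ArmEffect())


@dataclass
class PROGroundTruth:
    """Linear coupling of patient-reported outcomes to clock covariates.

    ``couplings[outcome][arm][covariate] = beta``; covariates are named
    ``<gene>_<parameter>`` (e.g. ``BMAL1_acrophase_h``) and refer to the
    patient's ground-truth rhythm parameters at that stage.
    """

    intercepts: dict[str, float] = field(default_factory=dict)
    couplings: dict = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for o, sd in self.residual_sd.items():
            if sd < 0:
                raise ValueError(f"residual sd for {o} must be >= 0")


@dataclass
class StepsGroundTruth:
    """Monthly mean step counts, negatively coupled to adverse-event score."""

    baseline_steps: float = 7000.0
    slope_per_ae: float = 400.0  # steps lost per AE-score point
    sd: float = 500.0
    n_months: int = 12
    ae_outcomes: tuple[str, ...] = ("nausea", "fatigue")


@dataclass
class PanelLaneTruth:
    """Per-lane technical factors and shared true transcript abundances."""

    positive_scale: np.ndarray  # one per lane, > 0
    background: np.ndarray  # additive counts per lane, >= 0
    housekeeping_factor: np.ndarray  # content factor per lane, > 0
    gene_log2_abundance: dict[str, float] = field(default_factory=dict)
    positive_base_counts: tuple[float, ...] = (8192, 2048, 512, 128, 32, 8)

    def __post_init__(self) -> None:
        self.positive_scale = np.asarray(self.positive_scale, float)
        self.background = np.asarray(self.background, float)
        self.housekeeping_factor = np.asarray(self.housekeeping_factor, float)
        if (self.positive_scale <= 0).any() or (self.housekeeping_factor <= 0).any():
            raise ValueError("lane factors must be positive")
        if (self.background < 0).any():
            raise ValueError("background must be non-negative")


@dataclass
class CohortBundle:
    """Generated dataset plus the ground truth that produced it."""

    timecourse: pd.DataFrame  # patient_id, arm, stage, gene, time_h, value
    pro: pd.DataFrame  # patient_id, arm, visit, outcome, score
    steps: pd.DataFrame  # patient_id, month, mean_steps
    ground_truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.timecourse.to_csv(out / "timecourse.csv", index=False)
        self.pro.to_csv(out / "pro.csv", index=False)
        self.steps.to_csv(out / "steps.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def default_clock_truth() -> ClockGroundTruth:
    """Three-gene qPCR panel on the mean-normalised relative-expression scale.

    BMAL1 evening-peaked, PER2 roughly antiphase, PARP1 intermediate; the
    treated arm acquires a phase advance and amplitude damping of the core
    clock genes at post-baseline stages.
    """
    return ClockGroundTruth(
        genes={
            "BMAL1": GeneRhythm(mesor=1.0, amplitude=0.4, acrophase_h=16.0, noise_sd=0.1),
            "PER2": GeneRhythm(mesor=1.0, amplitude=0.35, acrophase_h=5.0, noise_sd=0.1),
            "PARP1": GeneRhythm(mesor=1.0, amplitude=0.2, acrophase_h=12.0, noise_sd=0.1),
        },
        arm_effects={
            "BMAL1": ArmEffect(delta_acrophase_h=-4.0, amplitude_scale=0.7),
            "PER2": ArmEffect(delta_acrophase_h=-3.0, amplitude_scale=0.8),
        },
    )


def default_pro_truth() -> PROGroundTruth:
    """Outcome scores (0-100 scale) with arm-opposed clock couplings."""
    cov = "BMAL1_acrophase_h"
    out = {}
    sd = {}
    coup = {}
    for outcome, inter, beta_r, beta_p, s in [
        ("nausea", 20.0, -2.0, 2.0, 8.0),
        ("fatigue", 30.0, -2.5, 2.5, 8.0),
        ("insomnia", 25.0, -1.5, 1.5, 8.0),
        ("global_health", 70.0, 2.0, -2.0, 8.0),
        ("functional_scale", 75.0, 1.5, -1.5, 8.0),
    ]:
        out[outcome] = inter
        sd[outcome] = s
        coup[outcome] = {"rucaparib": {cov: beta_r}, "placebo": {cov: beta_p}}
    return PROGroundTruth(intercepts=out, couplings=coup, residual_sd=sd)


def _assign_arms(design: CohortDesign, rng: np.random.Generator) -> pd.Series:
    n_treated, n_placebo = design.arm_counts
    arms = np.array(["rucaparib"] * n_treated + ["placebo"] * n_placebo)
    rng.shuffle(arms)
    ids = [f"P{i + 1:03d}" for i in range(design.n_patients)]
    return pd.Series(arms, index=ids, name="arm")


def generate_cohort(
    design: CohortDesign,
    clock_truth: ClockGroundTruth | None = None,
    pro_truth: PROGroundTruth | None = None,
    steps_truth: StepsGroundTruth | None = None,
    _patient_acro_shift=None,
) -> CohortBundle:
    """Generate the full synthetic dataset bundle.

    Values follow ``mesor + amplitude * cos(2*pi*(t - acrophase)/24)`` plus
    noise at the (jittered) sampling times; arm effects apply only at
    post-baseline stages of the treated arm.  Returns data tables and a
    ground-truth record with the per patient x stage x gene parameters
    actually used.
    """
    clock_truth = clock_truth if clock_truth is not None else default_clock_truth()
    pro_truth = pro_truth if pro_truth is not None else default_pro_truth()
    steps_truth = steps_truth if steps_truth is not None else StepsGroundTruth()
    if not clock_truth.genes:
        raise ValueError("clock_truth must define at least one gene")
    for stage_needed in ("baseline",):
        if stage_needed not in design.stages:
            raise ValueError(f"design stages must include {stage_needed!r}")

    rng = np.random.default_rng(design.seed)
    arms = _assign_arms(design, rng)
    times = np.asarray(design.sample_times_h, float)

    tc_rows = []
    truth_rows = []
    pro_rows = []
    dropped = []

    for pid, arm in arms.items():
        # patient-level random effects, constant across stages
        acro_off = {
            g: rng.normal(0.0, clock_truth.patient_acrophase_sd_h)
            for g in clock_truth.genes
        }
        if _patient_acro_shift is not None and pid in _patient_acro_shift:
            for g in acro_off:
                acro_off[g] += _patient_acro_shift[pid]
        mesor_off = {
            g: rng.normal(0.0, clock_truth.patient_mesor_sd)
            for g in clock_truth.genes
        }
        amp_fac = {
            g: float(
                np.exp(rng.normal(0.0, clock_truth.patient_amplitude_rel_sd))
            )
            for g in clock_truth.genes
        }
        for stage in design.stages:
            treated_stage = arm == "rucaparib" and stage != "baseline"
            if (
                stage != "baseline"
                and design.dropout_prob > 0
                and rng.random() < design.dropout_prob
            ):
                dropped.append({"patient_id": pid, "stage": stage})
                continue
            stage_params = {}
            for gene, base in clock_truth.genes.items():
                eff = (
                    clock_truth.effect_for(gene, stage)
                    if treated_stage
                    else ArmEffect()
                )
                mesor = base.mesor + mesor_off[gene] + eff.delta_mesor
                amplitude = base.amplitude * amp_fac[gene] * eff.amplitude_scale
                acrophase = (
                    base.acrophase_h + acro_off[gene] + eff.delta_acrophase_h
                ) % 24.0
                stage_params[gene] = (mesor, amplitude, acrophase, base.noise_sd)

                if design.time_jitter_sd_h > 0:
                    jitter = np.clip(
                        rng.normal(0.0, design.time_jitter_sd_h, size=times.size),
                        -1.0,
                        1.0,
                    )
                else:
                    jitter = np.zeros(times.size)
                t = times + jitter
                clean = mesor + amplitude * np.cos(2 * np.pi * (t - acrophase) / 24.0)
                if base.noise_sd > 0:
                    if clock_truth.noise_model == "lognormal":
                        vals = clean * np.exp(
                            rng.normal(0.0, base.noise_sd, size=t.size)
                        )
                    else:
                        vals = clean + rng.normal(0.0, base.noise_sd, size=t.size)
                else:
                    vals = clean
                for ti, vi in zip(t, vals):
                    tc_rows.append(
                        {
                            "patient_id": pid,
                            "arm": arm,
                            "stage": stage,
                            "gene": gene,
                            "time_h": float(ti),
                            "value": float(vi),
                        }
                    )
                truth_rows.append(
                    {
                        "patient_id": pid,
                        "arm": arm,
                        "stage": stage,
                        "gene": gene,
                        "mesor": mesor,
                        "amplitude": amplitude,
                        "acrophase_h": acrophase,
                        "noise_sd": base.noise_sd,
                    }
                )

            # PRO scores for this visit, driven by the true stage parameters
            covariates = {}
            for gene, (mesor, amplitude, acrophase, _) in stage_params.items():
                covariates[f"{gene}_mesor"] = mesor
                covariates[f"{gene}_amplitude"] = amplitude
                covariates[f"{gene}_acrophase_h"] = acrophase
            for outcome, intercept in pro_truth.intercepts.items():
                betas = pro_truth.couplings.get(outcome, {}).get(arm, {})
                score = intercept + sum(
                    b * covariates[c] for c, b in betas.items()
                )
                score += rng.normal(0.0, pro_truth.residual_sd.get(outcome, 0.0))
                pro_rows.append(
                    {
                        "patient_id": pid,
                        "arm": arm,
                        "visit": stage,
                        "outcome": outcome,
                        "score": float(score),
                    }
                )

    timecourse = pd.DataFrame(
        tc_rows, columns=["patient_id", "arm", "stage", "gene", "time_h", "value"]
    )
    pro = pd.DataFrame(
        pro_rows, columns=["patient_id", "arm", "visit", "outcome", "score"]
    )

    # monthly steps: baseline minus slope x AE score (+ noise)
    step_rows = []
    ae = (
        pro[pro["outcome"].isin(steps_truth.ae_outcomes)]
        .groupby("patient_id")["score"]
        .mean()
    )
    for pid in arms.index:
        ae_score = float(ae.get(pid, 0.0)) / 10.0  # 0-100 scale -> 0-10 score
        for month in range(1, steps_truth.n_months + 1):
            mean_steps = (
                steps_truth.baseline_steps
                - steps_truth.slope_per_ae * ae_score
                + (rng.normal(0.0, steps_truth.sd) if steps_truth.sd > 0 else 0.0)
            )
            step_rows.append(
                {
                    "patient_id": pid,
                    "month": month,
                    "mean_steps": float(mean_steps),
                }
            )
    steps = pd.DataFrame(step_rows)

    ground_truth = {
        "design": asdict(design),
        "arms": arms.to_dict(),
        "rhythm_parameters": truth_rows,
        "pro_truth": {
            "intercepts": pro_truth.intercepts,
            "couplings": pro_truth.couplings,
            "residual_sd": pro_truth.residual_sd,
        },
        "steps_truth": asdict(steps_truth),
        "dropped_samples": dropped,
    }
    return CohortBundle(timecourse, pro, steps, ground_truth)


def generate_bimodal_phase_cohort(
    design: CohortDesign,
    fraction_advanced: float,
    advance_h: float,
    clock_truth: ClockGroundTruth | None = None,
    pro_truth: PROGroundTruth | None = None,
) -> CohortBundle:
    """Cohort whose treated arm splits into phase-advanced and unchanged subgroups.

    A fraction of treated patients has every gene's acrophase advanced
    (shifted earlier) by ``advance_h`` at all stages; the placebo arm stays
    unimodal.  The advanced subgroup is recorded in the ground truth.
    """
    if not 0 <= fraction_advanced <= 1:
        raise ValueError("fraction_advanced must lie in [0, 1]")
    if not 0 < advance_h < 24:
        raise ValueError("advance_h must lie strictly between 0 and 24 h")
    rng = np.random.default_rng(design.seed)
    arms = _assign_arms(design, rng)
    treated = [p for p, a in arms.items() if a == "rucaparib"]
    n_adv = int(round(fraction_advanced * len(treated)))
    advanced = list(rng.choice(treated, size=n_adv, replace=False)) if n_adv else []
    shifts = {pid: -advance_h for pid in advanced}
    bundle = generate_cohort(
        design, clock_truth, pro_truth, _patient_acro_shift=shifts
    )
    bundle.ground_truth["advanced_subgroup"] = sorted(advanced)
    bundle.ground_truth["advance_h"] = advance_h
    return bundle


def generate_panel_counts(
    lane_truth: PanelLaneTruth,
    probe_manifest: pd.Series,
    seed: int | None = None,
    noise: str = "none",
) -> tuple[PanelCountMatrix, dict]:
    """Raw lane x probe integer counts from known lane factors.

    Endogenous and housekeeping probes yield
    ``round(pos_scale * hk_factor * 2^log2_abundance + background)``;
    positive controls follow a fixed count ladder scaled by the lane factor;
    negative controls carry background only.  With ``noise='poisson'`` counts
    are Poisson draws around those expectations.

    Returns the count matrix and the ground-truth factor record.
    """
    classes = probe_manifest
    for cls in ("positive", "negative", "housekeeping"):
        if not (classes == cls).any():
            raise ValueError(f"probe manifest needs at least one {cls!r} probe")
    n_lanes = lane_truth.positive_scale.size
    if lane_truth.background.size != n_lanes or lane_truth.housekeeping_factor.size != n_lanes:
        raise ValueError("lane factor arrays must have equal length")
    rng = np.random.default_rng(seed)

    lanes = [f"L{i + 1:02d}" for i in range(n_lanes)]
    pos_probes = list(classes.index[classes == "positive"])
    ladder = list(lane_truth.positive_base_counts)
    expected = pd.DataFrame(0.0, index=lanes, columns=classes.index)
    for i, lane in enumerate(lanes):
        ps = lane_truth.positive_scale[i]
        bg = lane_truth.background[i]
        hk = lane_truth.housekeeping_factor[i]
        for j, probe in enumerate(pos_probes):
            expected.loc[lane, probe] = ps * ladder[j % len(ladder)] + bg
        for probe in classes.index[classes == "negative"]:
            expected.loc[lane, probe] = bg
        for probe in classes.index[classes.isin(["housekeeping", "endogenous"])]:
            if probe not in lane_truth.gene_log2_abundance:
                raise ValueError(f"no true abundance for probe {probe!r}")
            ab = 2.0 ** lane_truth.gene_log2_abundance[probe]
            expected.loc[lane, probe] = ps * hk * ab + bg

    if noise == "poisson":
        counts = rng.poisson(expected.to_numpy()).astype(float)
    elif noise == "none":
        counts = np.round(expected.to_numpy())
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    matrix = PanelCountMatrix(
        pd.DataFrame(counts, index=lanes, columns=classes.index), classes.copy()
    )
    truth = {
        "positive_scale": dict(zip(lanes, lane_truth.positive_scale)),
        "background": dict(zip(lanes, lane_truth.background)),
        "housekeeping_factor": dict(zip(lanes, lane_truth.housekeeping_factor)),
        "gene_log2_abundance": dict(lane_truth.gene_log2_abundance),
        "noise": noise,
        "seed": seed,
    }
    return matrix, truth
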