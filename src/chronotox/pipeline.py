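"""End-to-end orchestration: simulate -> rhythmometry -> differential ->
model personalisation -> toxicity -> associations -> clusters.

The pipeline is a pure function of (inputs, configuration, seeds): every
stochastic stage carries an explicit seed derived from the run seed, and the
machine-readable report records the configuration hash alongside per-stage
summaries so identical configurations yield identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .cohort import (
    CohortDesign,
    CohortBundle,
    default_clock_truth,
    default_pro_truth,
    generate_cohort,
)
from .rhythm import SalivaTimecourse, fit_timecourse
from .differential import differential_rhythmicity, differential_expression
from .association import ols_bootstrap, spearman_bootstrap
from .stratify import kmeans_stratify, evaluate_arm_recovery
from .errors import ChronotoxError, InsufficientDataError, DegenerateDesignError
from .clockmodel import default_parameters, toxicity_profile
from .personalise import EAConfig, fit_patient, aligned_parameters

logger = logging.getLogger("chronotox")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Stage toggles plus the parameters of each stage.  Defaults follow the
    study conventions: 24-h period, p < 0.05 with |logFC| >= 0.2, 4-h phase
    cut, 25,000 OLS bootstrap resamples, 07:00 wake time.
    """

    seed: int = 0
    out_dir: str | None = None
    # stage toggles
    simulate: bool = True
    cosinor: bool = True
    diffrhythm: bool = True
    associations: bool = True
    clusters: bool = True
    model_fit: bool = False  # EA personalisation + toxicity (slow)
    # stage parameters
    n_patients: int = 42
    stages: tuple[str, ...] = ("baseline", "W4", "W12", "M6", "M12", "EOT")
    period_h: float = 24.0
    min_points: int = 3
    p_cut: float = 0.05
    lfc_cut: float = 0.2
    phase_cut_h: float = 4.0
    amp_rel_cut: float = 0.5
    ols_n_boot: int = 25000
    spearman_n_boot: int = 2000
    spearman_n_perm: int = 10000
    k_range: tuple[int, int] = (2, 6)
    kmeans_n_init: int = 50
    cluster_features: tuple[str, ...] = ("BMAL1_acrophase_h", "BMAL1_mesor")
    ea_generations: int = 60
    model_fit_max_patients: int = 2
    toxicity_dose: float = 1.0
    toxicity_regimen: str = "single"
    input_dir: str | None = None  # read tables here instead of simulating

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "k_range", "cluster_features"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def fit_cosinor_table(
    timecourse: pd.DataFrame, period_h: float = 24.0, min_points: int = 3
) -> pd.DataFrame:
    """One cosinor fit per patient x stage x gene of a tidy time-course table."""
    rows = []
    for (pid, arm, stage, gene), grp in timecourse.groupby(
        ["patient_id", "arm", "stage", "gene"], sort=True
    ):
        if len(grp) < min_points:
            continue
        series = SalivaTimecourse(
            pid, arm, stage, gene,
            grp["time_h"].to_numpy(), grp["value"].to_numpy(),
        )
        try:
            fit = fit_timecourse(series, period_h=period_h)
        except (InsufficientDataError, DegenerateDesignError) as err:
            logger.warning("skipping %s/%s/%s: %s", pid, stage, gene, err)
            continue
        rows.append(
            {
                "patient_id": pid,
                "arm": arm,
                "stage": stage,
                "gene": gene,
                "mesor": fit.mesor,
                "amplitude": fit.amplitude,
                "acrophase_h": fit.acrophase_h,
                "rhythm_p": fit.rhythm_p,
                "n_points": fit.n_points,
                "low_confidence": fit.low_confidence,
            }
        )
    return pd.DataFrame(rows)


def _run_diffrhythm(timecourse: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Per patient x gene: post-baseline stages vs baseline rhythm change."""
    rows = []
    for (pid, gene), grp in timecourse.groupby(["patient_id", "gene"]):
        base = grp[grp["stage"] == "baseline"]
        if len(base) < 3:
            continue
        for stage in [s for s in cfg.stages if s != "baseline"]:
            cur = grp[grp["stage"] == stage]
            if len(cur) < 3:
                continue
            try:
                res = differential_rhythmicity(
                    base["time_h"], base["value"], cur["time_h"], cur["value"],
                    gene=gene, period_h=cfg.period_h,
                    alpha=cfg.p_cut, phase_cut_h=cfg.phase_cut_h,
                    amp_rel_cut=cfg.amp_rel_cut,
                )
            except DegenerateDesignError:
                continue
            rows.append(
                {
                    "patient_id": pid,
                    "gene": gene,
                    "stage": stage,
                    "arm": grp["arm"].iloc[0],
                    "delta_phase_h": res.delta_phase,
                    "rel_amp_change": res.rel_amp_change,
                    "interaction_p": res.interaction_p,
                    "flagged": res.flagged,
                }
            )
    return pd.DataFrame(rows)


def _run_associations(
    fits: pd.DataFrame, pro: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    """Patient-level bootstrap OLS of PRO outcomes on clock covariates per arm.

    Repeated kits are aggregated to patient level by the mean (configurable
    aggregation is a documented package choice)."""
    seed = _stage_seed(cfg.seed, "associations")
    cov = (
        fits.pivot_table(
            index=["patient_id", "arm"],
            columns="gene",
            values=["mesor", "amplitude", "acrophase_h"],
            aggfunc="mean",
        )
    )
    cov.columns = [f"{g}_{p}" for p, g in cov.columns]
    pro_wide = pro.pivot_table(
        index=["patient_id", "arm"], columns="outcome", values="score",
        aggfunc="mean",
    )
    merged = cov.join(pro_wide, how="inner").reset_index()
    rows = []
    outcomes = list(pro_wide.columns)
    covariates = [c for c in cov.columns if c in merged.columns]
    for arm, grp in merged.groupby("arm"):
        for outcome in outcomes:
            for covariate in covariates:
                sub = grp[[covariate, outcome]].dropna()
                if len(sub) < 4:
                    continue
                x = sub[covariate].to_numpy()
                y = sub[outcome].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                res = ols_bootstrap(
                    y, x, n_boot=cfg.ols_n_boot, seed=seed,
                    coef_names=[covariate],
                )
                rho = spearman_bootstrap(
                    x, y, n_boot=cfg.spearman_n_boot,
                    n_perm=cfg.spearman_n_perm, seed=seed,
                )
                rows.append(
                    {
                        "arm": arm,
                        "outcome": outcome,
                        "covariate": covariate,
                        "beta": res.estimates[1],
                        "beta_ci_low": res.ci_low[1],
                        "beta_ci_high": res.ci_high[1],
                        "p_boot": res.p_boot[1],
                        "adj_r_squared": res.adj_r_squared,
                        "spearman_rho": rho.estimate,
                        "rho_ci_low": rho.ci_low,
                        "rho_ci_high": rho.ci_high,
                        "p_perm": rho.p_resampled,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(rows)


def _run_clusters(fits: pd.DataFrame, cfg: RunConfig) -> dict:
    seed = _stage_seed(cfg.seed, "clusters")
    cov = fits.pivot_table(
        index=["patient_id", "arm"], columns="gene",
        values=["mesor", "amplitude", "acrophase_h"], aggfunc="mean",
    )
    cov.columns = [f"{g}_{p}" for p, g in cov.columns]
    cov = cov.reset_index().set_index("patient_id")
    feats = [f for f in cfg.cluster_features if f in cov.columns]
    if len(feats) < 1:
        raise ChronotoxError(
            f"none of the requested cluster features {cfg.cluster_features} "
            "are available"
        )
    table = cov[feats].dropna()
    result = kmeans_stratify(
        table, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
        n_init=cfg.kmeans_n_init, seed=seed,
    )
    arm = cov.loc[table.index, "arm"]
    recovery = evaluate_arm_recovery(result, arm)
    return {
        "k": result.k,
        "silhouette_mean": result.silhouette_mean,
        "features": feats,
        "assignments": result.assignments.to_dict(),
        "per_k": result.per_k.to_dict(orient="records"),
        "arm_fisher_p": recovery["fisher_p"],
        "arm_purity": recovery["purity"],
    }


def _run_model_fit(timecourse: pd.DataFrame, cfg: RunConfig) -> list[dict]:
    reference = default_parameters()
    seed = _stage_seed(cfg.seed, "model_fit")
    summaries = []
    patients = sorted(timecourse["patient_id"].unique())[: cfg.model_fit_max_patients]
    for pid in patients:
        sub = timecourse[
            (timecourse["patient_id"] == pid)
            & (timecourse["stage"] == "baseline")
        ]
        genes = {g: grp for g, grp in sub.groupby("gene")}
        if "BMAL1" not in genes or "PER2" not in genes:
            continue
        mk = lambda g: SalivaTimecourse(
            pid, sub["arm"].iloc[0], "baseline", g,
            genes[g]["time_h"].to_numpy(), genes[g]["value"].to_numpy(),
        )
        fit = fit_patient(
            mk("BMAL1"), mk("PER2"), reference,
            ea_config=EAConfig(generations=cfg.ea_generations),
            seed=seed,
        )
        profile = toxicity_profile(
            aligned_parameters(fit), dose=cfg.toxicity_dose,
            regimen=cfg.toxicity_regimen,
        )
        summaries.append(
            {
                "patient_id": pid,
                "objective": fit.objective,
                "phase_shift_h": fit.phase_shift_vs_reference_h,
                "converged": fit.converged,
                "average_toxicity": profile.average_toxicity,
                "relative_amplitude": profile.relative_amplitude,
                "absolute_amplitude": profile.absolute_amplitude,
                "phase_min_h": profile.phase_min_h,
            }
        )
    return summaries


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the report.

    When ``config.out_dir`` is set, intermediate tables and the report JSON
    are written there; partial outputs are preserved if a later stage fails.
    """
    t_start = time.time()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def persist(name: str, frame: pd.DataFrame) -> None:
        if out is not None and frame is not None:
            frame.to_csv(out / f"{name}.csv", index=False)

    def finish(stage: str, payload: dict, t0: float) -> None:
        payload["elapsed_s"] = round(time.time() - t0, 3)
        report["stages"][stage] = payload
        logger.info("stage %s done in %.2fs", stage, payload["elapsed_s"])

    try:
        # --- inputs -----------------------------------------------------
        t0 = time.time()
        if config.input_dir is not None:
            src = Path(config.input_dir)
            timecourse = pd.read_csv(src / "timecourse.csv")
            pro = pd.read_csv(src / "pro.csv")
            finish("load", {"source": str(src), "n_rows": len(timecourse)}, t0)
        elif config.simulate:
            design = CohortDesign(
                n_patients=config.n_patients,
                stages=config.stages,
                seed=_stage_seed(config.seed, "simulate"),
            )
            bundle = generate_cohort(
                design, default_clock_truth(), default_pro_truth()
            )
            timecourse, pro = bundle.timecourse, bundle.pro
            persist("timecourse", timecourse)
            persist("pro", pro)
            persist("steps", bundle.steps)
            finish(
                "simulate",
                {
                    "n_patients": config.n_patients,
                    "n_samples": len(timecourse),
                    "stage_seed": design.seed,
                },
                t0,
            )
        else:
            raise ChronotoxError("no inputs: enable simulate or set input_dir")

        fits = None
        if config.cosinor:
            t0 = time.time()
            fits = fit_cosinor_table(
                timecourse, period_h=config.period_h, min_points=config.min_points
            )
            persist("cosinor_fits", fits)
            finish(
                "cosinor",
                {
                    "n_fits": len(fits),
                    "n_low_confidence": int(fits["low_confidence"].sum()),
                },
                t0,
            )

        if config.diffrhythm:
            t0 = time.time()
            dr = _run_diffrhythm(timecourse, config)
            persist("diffrhythm", dr)
            finish(
                "diffrhythm",
                {
                    "n_comparisons": len(dr),
                    "n_flagged": int(dr["flagged"].sum()) if len(dr) else 0,
                },
                t0,
            )

        if config.associations:
            if fits is None:
                raise ChronotoxError("associations require the cosinor stage")
            t0 = time.time()
            assoc = _run_associations(fits, pro, config)
            persist("associations", assoc)
            finish("associations", {"n_tests": len(assoc)}, t0)

        if config.clusters:
            if fits is None:
                raise ChronotoxError("clusters require the cosinor stage")
            t0 = time.time()
            finish("clusters", _run_clusters(fits, config), t0)

        if config.model_fit:
            t0 = time.time()
            finish(
                "model_fit",
                {"patients": _run_model_fit(timecourse, config)},
                t0,
            )
    except Exception as err:
        report["error"] = f"{type(err).__name__}: {err}"
        if out is not None:
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=1, default=_coerce)
        raise

    report["elapsed_s"] = round(time.time() - t_start, 3)
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_coerce)
    return report


def _coerce(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# --- input validation ---------------------------------------------------------

_SCHEMAS = {
    "timecourse.csv": {
        "required": ["patient_id", "arm", "stage", "gene", "time_h", "value"],
        "numeric": ["time_h", "value"],
    },
    "pro.csv": {
        "required": ["patient_id", "arm", "visit", "outcome", "score"],
        "numeric": ["score"],
    },
    "steps.csv": {
        "required": ["patient_id", "month", "mean_steps"],
        "numeric": ["month", "mean_steps"],
    },
    "panel_counts.csv": {
        "required": ["lane_id", "probe_id", "probe_class", "count"],
        "numeric": ["count"],
    },
}


def validate_inputs(paths) -> list[dict]:
    """Schema-check CSV inputs; returns a list of violations (empty if clean).

    Checks required columns, numeric types, clock-time and count ranges, and
    duplicated (patient, stage, gene, time) sampling rows.
    """
    violations = []

    def add(path, kind, detail):
        violations.append({"file": str(path), "kind": kind, "detail": detail})

    for path in paths:
        path = Path(path)
        schema = _SCHEMAS.get(path.name)
        if schema is None:
            add(path, "unknown_file", "no schema registered for this file name")
            continue
        if not path.exists():
            add(path, "missing_file", "file does not exist")
            continue
        try:
            table = pd.read_csv(path)
        except Exception as err:
            add(path, "unreadable", str(err))
            continue
        missing = [c for c in schema["required"] if c not in table.columns]
        if missing:
            add(path, "missing_columns", ",".join(missing))
            continue
        for col in schema["numeric"]:
            vals = pd.to_numeric(table[col], errors="coerce")
            n_bad = int(vals.isna().sum() - table[col].isna().sum())
            if n_bad:
                add(path, "non_numeric", f"{col}: {n_bad} values")
        if path.name == "timecourse.csv":
            t = pd.to_numeric(table["time_h"], errors="coerce")
            bad = table[(t < 0) | (t > 48)]
            for _, row in bad.iterrows():
                add(path, "time_range", f"time_h={row['time_h']} outside [0, 48]")
            dup = table.duplicated(
                subset=["patient_id", "stage", "gene", "time_h"], keep=False
            )
            if dup.any():
                add(path, "duplicate_samples", f"{int(dup.sum())} rows")
        if path.name == "panel_counts.csv":
            c = pd.to_numeric(table["count"], errors="coerce")
            if (c < 0).any():
                add(path, "negative_counts", f"{int((c < 0).sum())} rows")
    return violations
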