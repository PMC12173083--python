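"""Per-patient personalisation of the clock model by an evolutionary strategy.

The freed parameter subset (:data:`chronotox.clockmodel.FREED_PARAMETERS`) is
fitted so that the simulated *Bmal1*/*Per2* mRNA profiles, sampled at the
patient's saliva collection clock times and mean-normalised per gene, match
the mean-normalised measured expression in root-mean-square error.  A
(mu + lambda) evolutionary strategy with log-normal multiplicative mutation
searches within [0.1x, 10x] of the reference values; the initial population
contains the reference set and time-rescaled variants of it (periods slightly
off 24 h accumulate phase shifts across the burn-in, giving the search a
direct handle on circadian phase).

Model time 0 corresponds to 07:00 wake time; measurement clock times are
converted accordingly.  After fitting, the BMAL1 acrophase of the fitted
limit cycle is extracted by cosinor and its circular difference to the
reference model's acrophase is the patient's phase shift, used to align the
PK/PD circadian gates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint

from .clockmodel import (
    ClockParameterSet,
    ClockState,
    FREED_PARAMETERS,
    WAKE_TIME_H,
    _make_rhs,
    align_to_clock_time,
    model_to_clock_time,
)
from .errors import IntegrationError
from .rhythm import SalivaTimecourse, cosinor_fit, circular_phase_difference

__all__ = ["EAConfig", "PersonalisedFit", "fit_patient", "aligned_parameters",
           "reference_profiles"]


@dataclass
class EAConfig:
    """Hyper-parameters of the (mu + lambda) evolutionary strategy."""

    mu: int = 10
    lam: int = 30
    generations: int = 200
    mutation_sigma: float = 0.15  # log-scale sd of multiplicative mutation
    mutation_prob: float = 0.35  # per-parameter mutation probability
    bounds: tuple[float, float] = (0.1, 10.0)  # x reference, per parameter
    early_stop_objective: float = 1e-4
    patience: int = 40  # generations without improvement before stopping
    burn_in_periods: int = 10
    rtol: float = 1e-8
    timescale_seed_offsets_h: tuple[float, ...] = (
        -0.6, -0.4, -0.2, 0.2, 0.4, 0.6,
    )


@dataclass
class PersonalisedFit:
    """Result of fitting the freed parameters to one patient's profiles."""

    parameters: ClockParameterSet
    objective: float  # RMSE on mean-normalised expression
    fitted_bmal1_phase_h: float  # local clock hours
    reference_bmal1_phase_h: float
    phase_shift_vs_reference_h: float  # signed circular difference
    seed: int | None
    generations_used: int
    n_evaluations: int
    converged: bool


def _model_times(series: SalivaTimecourse, wake_time_h: float) -> np.ndarray:
    tm = series.times_h - wake_time_h
    if tm.min() < -24.0 or tm.max() > 72.0:
        raise ValueError(
            "sample clock times fall outside the supported two-day window"
        )
    if tm.min() < 0:
        # the limit cycle is 24-h periodic, so whole-period shifts are neutral
        tm = tm + 24.0 * math.ceil(-tm.min() / 24.0)
    return tm


def _sample_profiles(
    params: ClockParameterSet,
    model_times: np.ndarray,
    burn_in_h: float,
    rtol: float,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Simulated (m_B, m_P) at burn-in + model_times; None if degenerate."""
    t_eval = np.concatenate([[0.0], burn_in_h + np.sort(model_times)])
    order = np.argsort(model_times)
    rhs = _make_rhs(params)
    try:
        sol, info = odeint(
            rhs, ClockState().as_array(), t_eval,
            rtol=rtol, atol=1e-10, full_output=True, mxstep=100000,
        )
    except Exception:
        return None
    if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
        return None
    m_B = np.empty(model_times.size)
    m_P = np.empty(model_times.size)
    m_B[order] = sol[1:, 0]
    m_P[order] = sol[1:, 1]
    return m_B, m_P


def _normalise(v: np.ndarray) -> np.ndarray | None:
    m = v.mean()
    if not np.isfinite(m) or abs(m) < 1e-12:
        return None
    return v / m


def _objective(
    params: ClockParameterSet,
    tm_b: np.ndarray,
    tm_p: np.ndarray,
    data_b: np.ndarray,
    data_p: np.ndarray,
    burn_in_h: float,
    rtol: float,
) -> float:
    prof_b = _sample_profiles(params, tm_b, burn_in_h, rtol)
    if prof_b is None:
        return float("inf")
    sim_b = _normalise(prof_b[0])
    if np.array_equal(tm_b, tm_p):
        sim_p = _normalise(prof_b[1])
    else:
        prof_p = _sample_profiles(params, tm_p, burn_in_h, rtol)
        if prof_p is None:
            return float("inf")
        sim_p = _normalise(prof_p[1])
    if sim_b is None or sim_p is None:
        return float("inf")
    resid = np.concatenate([sim_b - data_b, sim_p - data_p])
    return float(np.sqrt(np.mean(resid**2)))


def _bmal1_acrophase(
    params: ClockParameterSet, burn_in_h: float, rtol: float,
    wake_time_h: float,
) -> float:
    """BMAL1 acrophase (local clock hours) over the 48-h sampling window."""
    t = np.linspace(burn_in_h, burn_in_h + 48.0, 961)
    rhs = _make_rhs(params)
    sol, info = odeint(
        rhs, ClockState().as_array(), np.concatenate([[0.0], t]),
        rtol=rtol, atol=1e-10, full_output=True, mxstep=100000,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError("failed to simulate fitted model for phase extraction")
    fit = cosinor_fit(t - burn_in_h, sol[1:, 0], period_h=24.0)
    if fit.acrophase_h is None:
        raise IntegrationError("fitted model has no BMAL1 oscillation")
    return model_to_clock_time(fit.acrophase_h, wake_time_h)


def reference_profiles(
    reference: ClockParameterSet,
    clock_times_h: np.ndarray,
    burn_in_periods: int = 10,
    rtol: float = 1e-8,
    wake_time_h: float = WAKE_TIME_H,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-normalised reference-model (BMAL1, PER2) values at clock times.

    Convenience for building synthetic patients and self-consistency checks.
    """
    tm = np.asarray(clock_times_h, float) - wake_time_h
    tm = tm - math.floor(tm.min() / 24.0) * 24.0
    prof = _sample_profiles(reference, tm, burn_in_periods * 24.0, rtol)
    if prof is None:
        raise IntegrationError("reference model failed to simulate")
    nb, np_ = _normalise(prof[0]), _normalise(prof[1])
    if nb is None or np_ is None:
        raise IntegrationError("reference profiles are degenerate")
    return nb, np_


def fit_patient(
    series_bmal1: SalivaTimecourse,
    series_per2: SalivaTimecourse,
    reference: ClockParameterSet,
    ea_config: EAConfig | None = None,
    seed: int | None = 0,
    wake_time_h: float = WAKE_TIME_H,
) -> PersonalisedFit:
    """Fit the freed clock parameters to one patient's BMAL1/PER2 profiles.

    Both series are mean-normalised internally, so only the shape and timing
    of the rhythms matter, matching the preprocessing of the measured
    time-courses.  Identical seed, data and configuration reproduce the fit
    exactly.
    """
    cfg = ea_config or EAConfig()
    rng = np.random.default_rng(seed)
    burn_in_h = cfg.burn_in_periods * 24.0

    tm_b = _model_times(series_bmal1, wake_time_h)
    tm_p = _model_times(series_per2, wake_time_h)
    if tm_b.size < 3 or tm_p.size < 3:
        raise ValueError("need >= 3 samples per gene to personalise")
    span_lo = max(series_bmal1.times_h.min(), series_per2.times_h.min())
    span_hi = min(series_bmal1.times_h.max(), series_per2.times_h.max())
    if span_hi <= span_lo:
        raise ValueError("BMAL1 and PER2 series have non-overlapping time support")

    data_b = _normalise(np.asarray(series_bmal1.values, float))
    data_p = _normalise(np.asarray(series_per2.values, float))
    if data_b is None or data_p is None:
        raise ValueError("cannot mean-normalise measured series with zero mean")

    ref_vals = np.array([getattr(reference, n) for n in FREED_PARAMETERS])
    lo = cfg.bounds[0] * ref_vals
    hi = cfg.bounds[1] * ref_vals

    def to_params(vec: np.ndarray) -> ClockParameterSet:
        return reference.with_values(**dict(zip(FREED_PARAMETERS, vec)))

    def evaluate(vec: np.ndarray) -> float:
        return _objective(
            to_params(vec), tm_b, tm_p, data_b, data_p, burn_in_h, cfg.rtol
        )

    n_eval = 0
    population: list[tuple[float, np.ndarray]] = []

    def add(vec: np.ndarray) -> None:
        nonlocal n_eval
        n_eval += 1
        population.append((evaluate(vec), vec))

    # seed population: reference, time-rescaled variants, random mutants
    add(ref_vals.copy())
    for off in cfg.timescale_seed_offsets_h:
        factor = 24.0 / (24.0 + off)
        scaled = reference.rescale_time(factor)
        add(np.array([getattr(scaled, n) for n in FREED_PARAMETERS]))
    while len(population) < max(cfg.mu, 1 + len(cfg.timescale_seed_offsets_h)):
        vec = ref_vals * np.exp(rng.normal(0.0, cfg.mutation_sigma, ref_vals.size))
        add(np.clip(vec, lo, hi))

    population.sort(key=lambda fv: fv[0])
    best = initial_best = population[0][0]
    stall = 0
    generations_used = 0
    early = best <= cfg.early_stop_objective

    for gen in range(cfg.generations):
        if early:
            break
        generations_used = gen + 1
        parents = population[: cfg.mu]
        for _ in range(cfg.lam):
            _, parent = parents[rng.integers(0, len(parents))]
            child = parent.copy()
            mask = rng.random(child.size) < cfg.mutation_prob
            if not mask.any():
                mask[rng.integers(0, child.size)] = True
            child[mask] *= np.exp(rng.normal(0.0, cfg.mutation_sigma, mask.sum()))
            np.clip(child, lo, hi, out=child)
            add(child)
        population.sort(key=lambda fv: fv[0])
        population[:] = population[: cfg.mu]
        if population[0][0] < best - 1e-12:
            best = population[0][0]
            stall = 0
        else:
            stall += 1
        if best <= cfg.early_stop_objective:
            early = True
        if stall >= cfg.patience:
            break

    best_obj, best_vec = population[0]
    fitted = to_params(best_vec)
    fitted_phase = _bmal1_acrophase(fitted, burn_in_h, cfg.rtol, wake_time_h)
    ref_phase = _bmal1_acrophase(reference, burn_in_h, cfg.rtol, wake_time_h)
    shift = circular_phase_difference(fitted_phase, ref_phase, 24.0, signed=True)
    return PersonalisedFit(
        parameters=fitted,
        objective=best_obj,
        fitted_bmal1_phase_h=fitted_phase,
        reference_bmal1_phase_h=ref_phase,
        phase_shift_vs_reference_h=shift,
        seed=seed,
        generations_used=generations_used,
        n_evaluations=n_eval,
        converged=early or best_obj < initial_best - 1e-15,
    )


def aligned_parameters(fit: PersonalisedFit) -> ClockParameterSet:
    """Fitted parameters with the PK/PD gates shifted by the patient's phase."""
    return align_to_clock_time(fit.parameters, fit.phase_shift_vs_reference_h)
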