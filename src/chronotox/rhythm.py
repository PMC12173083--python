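"""Fixed-period cosinor (harmonic regression) rhythmometry.

A series of expression values sampled at known clock times is modelled as

    E(t) = MESOR + a*cos(omega*t) + b*sin(omega*t) + noise,   omega = 2*pi/period

equivalently ``MESOR + A*cos(omega*(t - acrophase))`` with amplitude
``A = sqrt(a^2 + b^2)`` and acrophase ``atan2(b, a)/omega`` (hours after local
midnight at which the fitted oscillation peaks).  The period is fixed (24 h by
default), so the fit is an ordinary least-squares problem with a closed-form
solution; no iteration is involved.

Also provides the qPCR preprocessing helpers used upstream of the fit
(delta-delta-Ct relative quantification, mean normalisation) and acrophase
binning for phase-distribution displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError

__all__ = [
    "SalivaTimecourse",
    "CosinorFit",
    "RelativeExpression",
    "cosinor_fit",
    "fit_timecourse",
    "acrophase_from_coeffs",
    "delta_delta_ct",
    "mean_normalise",
    "bin_acrophases",
    "circular_phase_difference",
]

#: below this fraction of |MESOR| (or this absolute value at MESOR == 0) the
#: fitted amplitude is treated as zero and the acrophase as undefined
_AMP_REL_EPS = 1e-9
_AMP_ABS_EPS = 1e-12

#: fits on fewer points than this are flagged low-confidence
_LOW_CONFIDENCE_N = 5


@dataclass
class SalivaTimecourse:
    """One patient x stage x gene expression time-course.

    ``times_h`` are clock/absolute hours (a two-day kit spans 0..48); phase
    angles wrap them onto one 24-h cycle.
    """

    patient_id: str
    arm: str
    stage: str
    gene: str
    times_h: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.shape != self.values.shape:
            raise ValueError("times_h and values must have the same length")
        if not np.all(np.isfinite(self.times_h)):
            raise ValueError("sample times must be finite")

    def phase_angles(self, period_h: float = 24.0) -> np.ndarray:
        """Phase angle of each sample in [0, 2*pi)."""
        return 2.0 * np.pi * np.mod(self.times_h, period_h) / period_h


@dataclass
class CosinorFit:
    """Circadian parameters estimated from one series."""

    mesor: float
    coeff_a: float
    coeff_b: float
    amplitude: float
    acrophase_h: float | None
    resid_sd: float
    rhythm_p: float
    n_points: int
    period_h: float = 24.0
    low_confidence: bool = False


@dataclass
class RelativeExpression:
    """2^-ddCt relative quantification of one target measurement."""

    delta_ct: float
    ddct: float
    fold_change: float


def acrophase_from_coeffs(a: float, b: float, period_h: float = 24.0) -> float | None:
    """Peak time of ``a*cos(w t) + b*sin(w t)`` in hours, wrapped to [0, period).

    Returns ``None`` when ``a == b == 0`` (no oscillation, undefined phase).
    """
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("cosinor coefficients must be finite")
    if a == 0.0 and b == 0.0:
        return None
    phi = (period_h / (2.0 * math.pi)) * math.atan2(b, a)
    phi %= period_h
    return 0.0 if phi >= period_h else phi  # tiny negatives can round to period


def cosinor_fit(
    times_h: Sequence[float] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    period_h: float = 24.0,
) -> CosinorFit:
    """Least-squares cosinor fit with fixed period.

    Parameters
    ----------
    times_h
        Sample clock times in hours (need not be sorted; two-day kits pool
        both days into one cycle through the periodic basis).
    values
        Expression values, same length as ``times_h``.
    period_h
        Fixed oscillation period; 24 h for circadian analyses.

    Returns
    -------
    CosinorFit
        MESOR, raw harmonic coefficients, amplitude, acrophase and a
        zero-amplitude F-test p-value (harmonic model vs intercept-only).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 points.
    DegenerateDesignError
        All points at one phase angle (rank-deficient design).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times_h and values must be 1-D and the same length")
    n = t.size
    if n < 3:
        raise InsufficientDataError(f"cosinor fit needs >= 3 points, got {n}")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
        raise ValueError("times and values must be finite")

    w = 2.0 * np.pi * t / period_h
    X = np.column_stack([np.ones(n), np.cos(w), np.sin(w)])
    # all points at one phase (mod period) leave cos/sin columns constant
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateDesignError(
            "degenerate cosinor design: samples cover < 2 distinct phase angles"
        )

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, a, b = (float(c) for c in beta)
    amplitude = math.hypot(a, b)

    resid = y - X @ beta
    sse1 = float(resid @ resid)
    dof = n - 3
    resid_sd = math.sqrt(sse1 / dof) if dof > 0 else 0.0

    # zero-amplitude test: F for the two harmonic terms jointly
    sse0 = float(np.sum((y - y.mean()) ** 2))
    if dof > 0 and sse1 > 0.0:
        f_stat = ((sse0 - sse1) / 2.0) / (sse1 / dof)
        rhythm_p = float(stats.f.sf(f_stat, 2, dof))
    elif sse0 <= sse1 * (1 + 1e-12) or (sse0 == 0.0 and sse1 == 0.0):
        rhythm_p = 1.0  # constant series: no evidence of rhythm
    else:
        rhythm_p = 0.0  # perfect harmonic fit of a non-constant series

    amp_floor = _AMP_REL_EPS * abs(mesor) if mesor != 0.0 else _AMP_ABS_EPS
    if amplitude < max(amp_floor, _AMP_ABS_EPS):
        acrophase = None
    else:
        acrophase = acrophase_from_coeffs(a, b, period_h)

    return CosinorFit(
        mesor=mesor,
        coeff_a=a,
        coeff_b=b,
        amplitude=amplitude,
        acrophase_h=acrophase,
        resid_sd=resid_sd,
        rhythm_p=min(max(rhythm_p, 0.0), 1.0),
        n_points=n,
        period_h=period_h,
        low_confidence=n < _LOW_CONFIDENCE_N,
    )


def fit_timecourse(series: SalivaTimecourse, period_h: float = 24.0) -> CosinorFit:
    """Cosinor fit of a :class:`SalivaTimecourse`."""
    return cosinor_fit(series.times_h, series.values, period_h=period_h)


def delta_delta_ct(
    ct_target: float, ct_reference: float, calibrator_delta_ct: float
) -> RelativeExpression:
    """Relative quantification by the 2^-ddCt method.

    ``dCt = Ct_target - Ct_reference`` (normalisation to the reference gene),
    ``ddCt = dCt - dCt_calibrator`` and ``fold_change = 2^-ddCt``.
    """
    for name, v in (
        ("ct_target", ct_target),
        ("ct_reference", ct_reference),
        ("calibrator_delta_ct", calibrator_delta_ct),
    ):
        if v is None or not math.isfinite(v):
            raise ValueError(f"{name} must be a finite Ct value (got {v!r})")
    dct = ct_target - ct_reference
    ddct = dct - calibrator_delta_ct
    return RelativeExpression(delta_ct=dct, ddct=ddct, fold_change=2.0 ** (-ddct))


def mean_normalise(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Divide a series by its own mean so the normalised series averages to 1."""
    y = np.asarray(values, dtype=float)
    m = y.mean()
    if m == 0.0:
        raise ValueError("cannot mean-normalise a series with zero mean")
    return y / m


def bin_acrophases(
    fits: Iterable[CosinorFit], bin_width_h: float = 4.0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of acrophases over [0, 24) in fixed-width bins.

    Binning is linear, not circular: 23.9 h and 0.1 h land in different bins.
    Undefined acrophases (zero-amplitude fits) are excluded from the counts
    and reported separately.

    Returns ``(counts, bin_edges, n_undefined)``.
    """
    n_bins = 24.0 / bin_width_h
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_width_h} h does not divide 24 h")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, 24.0, n_bins + 1)
    phases = [f.acrophase_h for f in fits]
    defined = np.array([p % 24.0 for p in phases if p is not None], dtype=float)
    counts, _ = np.histogram(defined, bins=edges)
    return counts, edges, len(phases) - defined.size


def circular_phase_difference(
    phase_a: float, phase_b: float, period_h: float = 24.0, signed: bool = False
) -> float:
    """Minimal circular difference between two phases in hours.

    Unsigned form is in [0, period/2]; signed form is in (-period/2, period/2]
    and measures ``phase_a - phase_b`` along the shorter arc.
    """
    d = (phase_a - phase_b) % period_h
    if d > period_h / 2.0:
        d -= period_h
    return d if signed else abs(d)
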