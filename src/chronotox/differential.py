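"""Two-group differential expression and differential rhythmicity.

Differential expression uses a plain per-gene two-sample t statistic on log2
values (pooled variance by default, Welch optional) with Benjamini-Hochberg
adjustment and the dual significance rule nominal p < 0.05 AND |logFC| >= 0.2.
Empirical-Bayes variance moderation is deliberately not applied; the plain
t-test is the documented stand-in and a moderated variant is left as an
extension point.

Differential rhythmicity compares two conditions' 24-h rhythms through a
joint harmonic regression with condition x harmonic interaction terms

    E = b0 + b1*cos(wt) + b2*sin(wt) + g*(b3 + b4*cos(wt) + b5*sin(wt))

where g is the condition indicator.  The two interaction harmonic terms are
tested jointly by an F-test; a gene is flagged when the interaction is
significant and the circadian parameters changed materially (phase shift
>= 4 h on the circular scale, or a relative amplitude change >= 50% by
default — the amplitude threshold is configurable and recorded in output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDesignError
from .rhythm import acrophase_from_coeffs, circular_phase_difference

__all__ = [
    "DEResult",
    "DiffRhythmResult",
    "differential_expression",
    "differential_rhythmicity",
    "bh_adjust",
]


@dataclass
class DEResult:
    gene: str
    log_fc: float
    p: float
    q: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass
class DiffRhythmResult:
    gene: str
    phase_a: float | None
    phase_b: float | None
    delta_phase: float
    amp_a: float
    amp_b: float
    delta_amp: float
    rel_amp_change: float
    interaction_p: float
    flagged: bool
    phase_cut_h: float
    amp_rel_cut: float


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    p_cut: float = 0.05,
    lfc_cut: float = 0.2,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group comparison of log2 expression matrices.

    Parameters
    ----------
    group_a, group_b
        samples x genes log2 matrices sharing the same gene columns.
    p_cut, lfc_cut
        Dual significance rule: nominal p < ``p_cut`` and |logFC| >= ``lfc_cut``.
    welch
        Use Welch's unequal-variance t-test instead of pooled variance.

    Returns a DataFrame with one row per gene: logFC (mean(A) - mean(B)),
    p, BH q, a classical 95% CI for the mean difference, and the significance
    flag.  Genes with zero variance in both groups and equal means get p = 1.
    """
    genes = list(group_a.columns)
    if list(group_b.columns) != genes:
        group_b = group_b[genes]
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")

    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    log_fc = m1 - m2

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            dof = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            dof = np.full_like(se2, float(n1 + n2 - 2))
        se = np.sqrt(se2)
        t_stat = log_fc / se

    p = np.empty_like(log_fc)
    finite = np.isfinite(t_stat)
    p[finite] = 2.0 * stats.t.sf(np.abs(t_stat[finite]), dof[finite])
    # zero variance in both groups: p = 1 on equal means, 0 on different means
    p[~finite & (log_fc == 0)] = 1.0
    p[~finite & (log_fc != 0)] = 0.0

    q = bh_adjust(p)
    tcrit = np.where(finite, stats.t.ppf(0.975, np.where(dof > 0, dof, 1)), 0.0)
    ci_low = log_fc - tcrit * np.where(finite, se, 0.0)
    ci_high = log_fc + tcrit * np.where(finite, se, 0.0)

    return pd.DataFrame(
        {
            "gene": genes,
            "log_fc": log_fc,
            "p": p,
            "q": q,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "significant": (p < p_cut) & (np.abs(log_fc) >= lfc_cut),
        }
    )


def _condition_params(
    beta: np.ndarray, condition: int, period_h: float
) -> tuple[float | None, float]:
    """Amplitude and acrophase implied by the joint model for one condition."""
    a = beta[1] + condition * beta[4]
    b = beta[2] + condition * beta[5]
    amp = float(np.hypot(a, b))
    return acrophase_from_coeffs(float(a), float(b), period_h), amp


def differential_rhythmicity(
    times_a,
    values_a,
    times_b,
    values_b,
    gene: str = "",
    period_h: float = 24.0,
    alpha: float = 0.05,
    phase_cut_h: float = 4.0,
    amp_rel_cut: float = 0.5,
) -> DiffRhythmResult:
    """Interaction test for a change in 24-h rhythm between two conditions.

    Fits the pooled harmonic model with condition main effect and
    condition x (cos, sin) interactions, tests the interaction pair by an
    F-test, and applies the decision rule: ``interaction_p < alpha`` AND
    (circular phase shift >= ``phase_cut_h`` OR relative amplitude change
    ``|dA| / max(A_a, A_b)`` >= ``amp_rel_cut``).
    """
    ta, ya = np.asarray(times_a, float), np.asarray(values_a, float)
    tb, yb = np.asarray(times_b, float), np.asarray(values_b, float)
    for label, t in (("A", ta), ("B", tb)):
        w = 2.0 * np.pi * t / period_h
        basis = np.column_stack([np.ones(t.size), np.cos(w), np.sin(w)])
        if t.size < 3 or np.linalg.matrix_rank(basis) < 3:
            raise DegenerateDesignError(
                f"series {label} is not individually fittable by cosinor"
            )

    t = np.concatenate([ta, tb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(ta.size), np.ones(tb.size)])
    w = 2.0 * np.pi * t / period_h
    X = np.column_stack(
        [np.ones(t.size), np.cos(w), np.sin(w), g, g * np.cos(w), g * np.sin(w)]
    )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse_full = float(resid @ resid)
    dof = t.size - 6

    X0 = X[:, :4]  # no interaction: shared rhythm, condition offset only
    beta0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
    sse_red = float((y - X0 @ beta0) @ (y - X0 @ beta0))
    if dof > 0 and sse_full > 0:
        f_stat = ((sse_red - sse_full) / 2.0) / (sse_full / dof)
        interaction_p = float(stats.f.sf(f_stat, 2, dof))
    else:
        interaction_p = 1.0 if sse_red <= sse_full * (1 + 1e-12) else 0.0

    phase_a, amp_a = _condition_params(beta, 0, period_h)
    phase_b, amp_b = _condition_params(beta, 1, period_h)
    if phase_a is not None and phase_b is not None:
        delta_phase = circular_phase_difference(phase_a, phase_b, period_h)
    else:
        delta_phase = 0.0
    delta_amp = amp_b - amp_a
    denom = max(amp_a, amp_b)
    rel_amp_change = abs(delta_amp) / denom if denom > 0 else 0.0

    flagged = interaction_p < alpha and (
        delta_phase >= phase_cut_h or rel_amp_change >= amp_rel_cut
    )
    return DiffRhythmResult(
        gene=gene,
        phase_a=phase_a,
        phase_b=phase_b,
        delta_phase=delta_phase,
        amp_a=amp_a,
        amp_b=amp_b,
        delta_amp=delta_amp,
        rel_amp_change=rel_amp_change,
        interaction_p=interaction_p,
        flagged=flagged,
        phase_cut_h=phase_cut_h,
        amp_rel_cut=amp_rel_cut,
    )
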