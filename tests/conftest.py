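import numpy as np
import pytest

from chronotox.clockmodel import default_parameters

#: the two-day saliva kit design: 9/13/17/21 h on two consecutive days
DESIGN_TIMES = np.array([9.0, 13.0, 17.0, 21.0, 33.0, 37.0, 41.0, 45.0])


@pytest.fixture(scope="session")
def design_times():
    return DESIGN_TIMES.copy()


@pytest.fixture(scope="session")
def reference_params():
    """The packaged calibrated clock parameter set (read once per session)."""
    return default_parameters()


def cosinor_curve(t, mesor, amplitude, acrophase_h, period_h=24.0):
    """Ground-truth cosinor curve used across tests."""
    return mesor + amplitude * np.cos(2 * np.pi * (t - acrophase_h) / period_h)


def cosinor_sse(t, y, amplitude, phase, period_h=24.0):
    """SSE of the cosinor curve with the MESOR profiled out (mean offset)."""
    c = np.cos(2 * np.pi * (t - phase) / period_h)
    resid = (y - y.mean()) - amplitude * (c - c.mean())
    return float(resid @ resid)


def grid_search_cosinor(t, y, amp_grid, phase_grid, period_h=24.0):
    """Independent brute-force oracle: exhaustive SSE over (A, phi) with the
    MESOR profiled out as the mean offset of the residual profile.

    Returns ``(A_best, phi_best, sse_best)`` over the full grid.
    """
    w = 2 * np.pi / period_h
    yc = y - y.mean()
    best = (np.inf, None, None)
    for phi in phase_grid:
        c = np.cos(w * (t - phi))
        cc = c - c.mean()
        syc = float(yc @ cc)
        scc = float(cc @ cc)
        sse = float(yc @ yc) - 2 * amp_grid * syc + amp_grid**2 * scc
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            best = (sse[j], amp_grid[j], phi)
    return best[1], best[2], best[0]
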