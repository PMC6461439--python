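"""Macroscopic current analyses.

Single-exponential relaxation fits (channel deactivation after ligand
removal, slow inactivation in maintained ligand), fractional-current
ratios between record segments, and the Hill fit of the ADPR
dose-response of macroscopic current activation.  Only single
exponentials are fitted; the baseline is a free parameter (seal leak is
not assumed zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import AssaySeries, Trace
from .enzyme import EnzymeFitResult, fit_hill

__all__ = [
    "RelaxationFit",
    "fit_exp_decay",
    "fractional_current",
    "fit_dose_response",
]


@dataclass
class RelaxationFit:
    amplitude: float
    tau: float
    baseline: float
    fit_window: tuple[float, float]
    residual_rms: float
    status: str = "ok"
    message: str = ""


def fit_exp_decay(trace: Trace, t_start: float = 0.0,
                  t_end: float | None = None) -> RelaxationFit:
    """Least-squares fit of I(t) = baseline + amplitude*exp(-(t-t_start)/tau).

    The fitted window runs from `t_start` (e.g. the solution-exchange
    time plus a safety margin) to `t_end` (default: end of record).  A
    window whose initial current magnitude does not exceed its final one
    yields a "failed" status.
    """
    t = trace.times
    lo = int(np.searchsorted(t, t_start))
    hi = trace.n_samples if t_end is None else int(np.searchsorted(t, t_end))
    if hi - lo < 10:
        raise ValueError("fit window contains fewer than 10 samples")
    tt = t[lo:hi] - t[lo]
    yy = trace.samples[lo:hi]
    n10 = max(hi - lo, 10) // 10
    head = float(np.mean(yy[:n10]))
    tail = float(np.mean(yy[-n10:]))
    if abs(head - tail) <= 1e-12 * max(1.0, abs(head)):
        return RelaxationFit(float("nan"), float("nan"), float("nan"),
                             (t_start, float(t[hi - 1])), float("nan"),
                             status="failed", message="window is not decaying")
    amp0 = head - tail
    # crude tau: time to decay to 1/e of the initial excess
    excess = np.abs(yy - tail)
    target = abs(amp0) / np.e
    below = np.flatnonzero(excess <= target)
    tau0 = float(tt[below[0]]) if below.size and below[0] > 0 else float(tt[-1] / 3)
    tau0 = max(tau0, tt[1] if len(tt) > 1 else 1e-3)

    def model(x, a, tau, b):
        return b + a * np.exp(-x / tau)

    try:
        popt, _ = curve_fit(model, tt, yy, p0=[amp0, tau0, tail], maxfev=20000)
    except RuntimeError as exc:
        return RelaxationFit(float("nan"), float("nan"), float("nan"),
                             (t_start, float(t[hi - 1])), float("nan"),
                             status="failed", message=str(exc))
    a, tau, b = (float(v) for v in popt)
    if tau <= 0:
        return RelaxationFit(a, tau, b, (t_start, float(t[hi - 1])), float("nan"),
                             status="failed", message="nonpositive fitted tau")
    resid = yy - model(tt, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    status, message = "ok", ""
    if tau > 10 * float(tt[-1]):
        status, message = "warning", "tau far exceeds the fitted window; poorly constrained"
    return RelaxationFit(a, tau, b, (t_start, float(t[hi - 1])), rms,
                         status=status, message=message)


def fractional_current(trace: Trace, test_window: tuple[float, float],
                       reference_window: tuple[float, float],
                       exclude_margin: float = 0.0) -> float:
    """Ratio of mean currents in a test vs a reference segment.

    `exclude_margin` (s) trims both window edges, e.g. to skip
    solution-exchange artifacts.  Scale-invariant by construction.
    """

    def window_mean(win: tuple[float, float]) -> float:
        a, b = win[0] + exclude_margin, win[1] - exclude_margin
        if not 0 <= a < b <= trace.duration + 1e-9:
            raise ValueError(f"window {win} (margin {exclude_margin}) outside trace span")
        lo = int(np.searchsorted(trace.times, a))
        hi = int(np.searchsorted(trace.times, b))
        if hi <= lo:
            raise ValueError(f"window {win} contains no samples after trimming")
        return float(np.mean(trace.samples[lo:hi]))

    ref = window_mean(reference_window)
    if ref == 0:
        raise ValueError("reference window mean is zero")
    return window_mean(test_window) / ref


def fit_dose_response(concentrations, fractional_currents) -> EnzymeFitResult:
    """Hill fit of fractional current activation vs agonist concentration.

    Returns k_half (K_1/2, uM), n_h and y_max via the shared Hill engine.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(fractional_currents, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any(y < 0):
        raise ValueError("fractional currents must be >= 0")
    series = AssaySeries(x=x, y=y, x_label="concentration_um",
                         y_label="fractional_current")
    return fit_hill(series)
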