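"""Conversion of sampled currents into idealized event lists.

Pipeline: zero-phase Gaussian low-pass filtering, baseline subtraction
(histogram mode of the closed level), half-amplitude threshold
idealization into integer conductance levels, optional dead-time
imposition, dwell extraction, and all-points-histogram estimation of the
unitary current amplitude as the mean spacing between adjacent Gaussian
peaks.

Half-amplitude assignment: after dividing by the (signed) unitary
amplitude, a sample belongs to level l when its value in unitary
multiples lies in (l - 1/2, l + 1/2]; a sample exactly at a
half-amplitude boundary therefore goes to the lower level.  The default
dead time after filtering at f_c is 0.179/f_c, the event-detection limit
of a Gaussian filter; no missed-event correction is applied downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.optimize import curve_fit

from .core import DwellTable, IdealizedRecord, Trace

__all__ = [
    "gaussian_lowpass",
    "gaussian_sigma_seconds",
    "default_dead_time",
    "subtract_baseline",
    "idealize",
    "impose_dead_time",
    "extract_dwells",
    "max_open_level",
    "AmplitudeHistogramFit",
    "fit_amplitude_histogram",
]


def gaussian_sigma_seconds(cutoff_hz: float) -> float:
    """Time-domain sigma of a Gaussian filter with -3 dB frequency `cutoff_hz`."""
    return math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)


def default_dead_time(cutoff_hz: float) -> float:
    """Event-detection limit of a Gaussian filter: 0.179 / f_c."""
    return 0.179 / cutoff_hz


def gaussian_lowpass(trace: Trace, cutoff: float) -> Trace:
    """Zero-phase Gaussian FIR low-pass with -3 dB point at `cutoff` (Hz).

    Attenuation of a sinusoid at f is exp(-ln2/2 * (f/f_c)^2), i.e.
    1/sqrt(2) at f = f_c; the 10-90% rise time of a filtered step is
    0.3321/f_c.
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyquist} Hz)")
    sigma_samples = gaussian_sigma_seconds(cutoff) * trace.sampling_rate
    out = ndimage.gaussian_filter1d(trace.samples, sigma_samples, mode="nearest",
                                    truncate=6.0)
    meta = {**trace.metadata, "filter_hz": cutoff}
    return Trace(out, trace.sampling_rate, filter_cutoff=cutoff, metadata=meta)


def _histogram_mode(x: np.ndarray, bin_width: float = 0.05) -> float:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < bin_width:
        return float(np.median(x))
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    k = int(np.argmax(counts))
    # refine: mean of samples within +/- 2 bins of the modal bin
    c = 0.5 * (edges[k] + edges[k + 1])
    sel = x[np.abs(x - c) <= 2 * bin_width]
    return float(np.mean(sel)) if sel.size else c


def subtract_baseline(trace: Trace, method: str = "mode",
                      max_offset: float = 1.5,
                      window_s: float | None = None) -> Trace:
    """Re-center the closed (zero-open) conductance level at 0 pA.

    The closed level is located as the histogram peak nearest 0 pA; if no
    peak lies within `max_offset` pA of zero the trace is returned
    unchanged with a warning (no identifiable closed level).  With
    `window_s` set, the baseline is re-estimated in consecutive windows
    and linearly interpolated between window centers, which corrects
    slow drift.
    """
    if method not in ("mode", "median"):
        raise ValueError("method must be 'mode' or 'median'")

    def estimate(x: np.ndarray) -> float | None:
        # candidate closed-level samples: near zero
        sel = x[np.abs(x) <= max_offset]
        if sel.size < max(10, 0.001 * x.size):
            return None
        return _histogram_mode(sel) if method == "mode" else float(np.median(sel))

    if window_s is None:
        base = estimate(trace.samples)
        if base is None:
            warnings.warn("no identifiable closed level near 0 pA; trace unchanged")
            return trace
        corrected = trace.samples - base
    else:
        n_win = max(int(round(trace.duration / window_s)), 2)
        splits = np.array_split(trace.samples, n_win)
        centers, values = [], []
        pos = 0
        for chunk in splits:
            b = estimate(chunk)
            if b is not None:
                centers.append(pos + chunk.size / 2.0)
                values.append(b)
            pos += chunk.size
        if not centers:
            warnings.warn("no identifiable closed level near 0 pA; trace unchanged")
            return trace
        baseline = np.interp(np.arange(trace.samples.size), centers, values)
        corrected = trace.samples - baseline
    meta = {**trace.metadata, "baseline_subtracted": True}
    return Trace(corrected, trace.sampling_rate, trace.filter_cutoff, meta)


def idealize(trace: Trace, unitary_amplitude: float, max_levels: int = 12) -> IdealizedRecord:
    """Half-amplitude threshold idealization into open-channel counts.

    Samples are expressed in multiples of the (signed) unitary amplitude
    so that levels count open channels regardless of current polarity;
    level l covers (l - 1/2, l + 1/2], the boundary going to the lower
    level.  Runs of equal level become events.
    """
    if unitary_amplitude == 0:
        raise ValueError("unitary_amplitude must be nonzero")
    r = trace.samples / unitary_amplitude
    levels = np.ceil(r - 0.5).astype(int)
    levels = np.maximum(levels, 0)
    over = levels > max_levels
    if np.any(over):
        k = int(np.argmax(over))
        raise ValueError(
            f"sample at t={k / trace.sampling_rate:.6g} s exceeds max_levels={max_levels}")
    # run-length encode
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [levels.size]])
    ev_levels = levels[starts]
    ev_durations = (ends - starts) / trace.sampling_rate
    return IdealizedRecord(ev_levels, ev_durations)


def impose_dead_time(record: IdealizedRecord, dead_time: float) -> IdealizedRecord:
    """Remove events shorter than `dead_time`, splitting their duration
    equally between the flanking events, then merge adjacent equal
    levels.  Total duration is conserved exactly; the operation is
    idempotent.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    levels = list(record.levels)
    durs = list(record.durations)
    if dead_time == 0 or not levels:
        return IdealizedRecord(np.asarray(levels), np.asarray(durs), dead_time=dead_time or None)
    changed = True
    while changed and len(levels) > 1:
        changed = False
        i = 0
        while i < len(levels):
            if durs[i] < dead_time and len(levels) > 1:
                d = durs[i]
                if i == 0:
                    durs[1] += d
                elif i == len(levels) - 1:
                    durs[i - 1] += d
                else:
                    durs[i - 1] += d / 2.0
                    durs[i + 1] += d / 2.0
                del levels[i], durs[i]
                # merge neighbours that now touch with equal level
                if 0 < i < len(levels) and levels[i - 1] == levels[i]:
                    durs[i - 1] += durs[i]
                    del levels[i], durs[i]
                changed = True
            else:
                i += 1
    return IdealizedRecord(np.asarray(levels), np.asarray(durs), dead_time=dead_time)


def extract_dwells(record: IdealizedRecord) -> DwellTable:
    """Per-level dwell lists and occupancy totals.

    The first and last events are censored by the record edges: they are
    excluded from the dwell lists but do count toward occupancy.
    """
    if record.n_events == 0:
        raise ValueError("record is empty")
    levels = record.levels
    durs = record.durations
    occupancy: dict[int, float] = {}
    for lvl in np.unique(levels):
        occupancy[int(lvl)] = float(durs[levels == lvl].sum())
    dwells: dict[int, np.ndarray] = {int(l): np.empty(0) for l in np.unique(levels)}
    if record.n_events > 2:
        inner_levels = levels[1:-1]
        inner_durs = durs[1:-1]
        for lvl in np.unique(inner_levels):
            dwells[int(lvl)] = inner_durs[inner_levels == lvl]
    return DwellTable(dwells=dwells, occupancy=occupancy, dead_time=record.dead_time)


def max_open_level(record: IdealizedRecord) -> int:
    """Highest conductance level present (the N' channel-count estimate)."""
    if record.n_events == 0:
        raise ValueError("record is empty")
    return int(record.levels.max())


@dataclass
class AmplitudeHistogramFit:
    peak_means: np.ndarray
    peak_sds: np.ndarray
    peak_weights: np.ndarray
    unitary_amplitude: float
    status: str = "ok"
    message: str = ""


def fit_amplitude_histogram(trace: Trace, max_components: int = 6,
                            n_bins: int = 400) -> AmplitudeHistogramFit:
    """Sum-of-Gaussians fit to the all-points histogram.

    The unitary current amplitude is the mean distance between adjacent
    peaks, signed so that it reports the current carried per open
    channel relative to the peak nearest the baseline (0 pA).  Data with
    fewer than two resolvable peaks yield a "failed" status (no spacing
    is defined).
    """
    x = trace.samples
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.gaussian_filter1d(counts.astype(float), 3.0)
    peak_idx, _ = signal.find_peaks(smooth, height=smooth.max() * 0.05,
                                    prominence=smooth.max() * 0.10, distance=5)
    if peak_idx.size < 2:
        return AmplitudeHistogramFit(np.empty(0), np.empty(0), np.empty(0),
                                     float("nan"), status="failed",
                                     message="fewer than two resolvable components")
    if peak_idx.size > max_components:
        order = np.argsort(smooth[peak_idx])[::-1][:max_components]
        peak_idx = np.sort(peak_idx[order])
    k = peak_idx.size
    bin_w = centers[1] - centers[0]
    spacing0 = np.mean(np.diff(centers[peak_idx])) if k > 1 else 10 * bin_w
    p0 = []
    for idx in peak_idx:
        p0.extend([smooth[idx], centers[idx], max(spacing0 / 6.0, bin_w)])

    def model(c, *p):
        out = np.zeros_like(c)
        for j in range(k):
            a, mu, sd = p[3 * j:3 * j + 3]
            out = out + a * np.exp(-0.5 * ((c - mu) / sd) ** 2)
        return out

    try:
        popt, _ = curve_fit(model, centers, counts.astype(float), p0=p0,
                            maxfev=20000)
    except RuntimeError as exc:
        return AmplitudeHistogramFit(np.empty(0), np.empty(0), np.empty(0),
                                     float("nan"), status="failed",
                                     message=f"mixture fit did not converge: {exc}")
    amps = np.abs(popt[0::3])
    means = popt[1::3]
    sds = np.abs(popt[2::3])
    order = np.argsort(means)
    amps, means, sds = amps[order], means[order], sds[order]
    weights = amps * sds
    weights = weights / weights.sum()
    spacings = np.diff(means)
    magnitude = float(np.mean(spacings))
    # sign: direction from the baseline peak (nearest zero) to the others
    base = means[int(np.argmin(np.abs(means)))]
    away = np.mean(means) - base
    unitary = -magnitude if away < 0 else magnitude
    return AmplitudeHistogramFit(means, sds, weights, unitary)
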