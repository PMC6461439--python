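"""Seeded synthetic-data generators for every pipeline input.

Produces exact continuous-time Markov-chain gating paths and their
rendered current traces, enzyme-assay rate tables with multiplicative
noise, single-exponential macroscopic relaxations, and toy protein
sequences carrying known motifs.  All generators are bit-reproducible
for a fixed seed.

Defaults mirror typical acquisition settings for this kind of recording:
10 kHz sampling with a 2 kHz recording filter.  Assay noise is
multiplicative (a fixed coefficient of variation), matching rate data
whose scatter grows with the signal; an additive mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AssaySeries, Trace
from .enzyme import CURVE_MODELS
from .gating import OPEN, GatingScheme, stationary_distribution
from .idealization import gaussian_lowpass

__all__ = [
    "GeneratorPreset",
    "ChannelPath",
    "simulate_ctmc",
    "render_trace",
    "paths_to_idealized",
    "generate_assay_series",
    "generate_relaxation",
    "generate_toy_sequences",
    "DEFAULT_SAMPLING_HZ",
    "DEFAULT_FILTER_HZ",
]

DEFAULT_SAMPLING_HZ = 10_000.0
DEFAULT_FILTER_HZ = 2_000.0


@dataclass
class GeneratorPreset:
    """Generating parameters for one synthetic assay series."""

    name: str
    curve_model: str
    params: dict[str, float]
    x_grid: Sequence[float]
    noise_cv: float = 0.0
    n_reps: int = 1
    seed: int = 0
    x_label: str = "x"
    noise_mode: str = "multiplicative"  # or "additive" (sd = noise_cv * model max)

    def __post_init__(self) -> None:
        if self.curve_model not in CURVE_MODELS:
            raise ValueError(
                f"unknown curve_model {self.curve_model!r}; expected one of {sorted(CURVE_MODELS)}")
        x = np.asarray(self.x_grid, dtype=float)
        if np.any(np.diff(x) < 0):
            raise ValueError("x_grid must be nondecreasing")
        if self.curve_model != "ph_titration" and np.any(x <= 0):
            raise ValueError("concentrations in x_grid must be strictly positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @classmethod
    def from_named(cls, name: str, noise_cv: float = 0.0, n_reps: int = 1,
                   seed: int = 0) -> "GeneratorPreset":
        from .presets import ENZYME_PRESETS
        if name not in ENZYME_PRESETS:
            raise KeyError(f"unknown preset {name!r}; known: {sorted(ENZYME_PRESETS)}")
        p = ENZYME_PRESETS[name]
        return cls(name=name, curve_model=p["curve_model"], params=dict(p["params"]),
                   x_grid=list(p["x_grid"]), noise_cv=noise_cv, n_reps=n_reps,
                   seed=seed, x_label=p.get("x_label", "x"))


@dataclass
class ChannelPath:
    """Exact event path of one channel: states and sojourn durations (s)."""

    states: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())


def simulate_ctmc(scheme: GatingScheme, n_channels: int, duration: float,
                  seed: int = 0) -> list[ChannelPath]:
    """Exact stochastic simulation of N independent channels.

    Each channel starts from the scheme's stationary distribution
    (steady-state records), draws exponential sojourns at the current
    state's total exit rate, and moves by competing-rate selection.  The
    final sojourn is truncated so each path sums exactly to `duration`.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    Q = scheme.rate_matrix()
    exit_rates = -np.diag(Q)
    pi = stationary_distribution(scheme)
    rng = np.random.default_rng(seed)
    paths = []
    for _ in range(n_channels):
        state = int(rng.choice(3, p=pi))
        t = 0.0
        states, durs = [], []
        while t < duration:
            rate = exit_rates[state]
            if rate <= 0:
                states.append(state)
                durs.append(duration - t)
                break
            sojourn = rng.exponential(1.0 / rate)
            if t + sojourn >= duration:
                states.append(state)
                durs.append(duration - t)
                break
            states.append(state)
            durs.append(sojourn)
            t += sojourn
            probs = Q[state].copy()
            probs[state] = 0.0
            probs /= probs.sum()
            state = int(rng.choice(3, p=probs))
        paths.append(ChannelPath(np.array(states), np.array(durs)))
    return paths


def open_count_per_sample(paths: list[ChannelPath], n_samples: int,
                          sampling_rate: float) -> np.ndarray:
    """Number of open channels at each sample time k/fs (left-continuous)."""
    t = np.arange(n_samples) / sampling_rate
    total = np.zeros(n_samples, dtype=int)
    for p in paths:
        bounds = np.cumsum(p.durations)
        idx = np.searchsorted(bounds, t, side="right")
        idx = np.minimum(idx, len(p.states) - 1)
        total += (p.states[idx] == OPEN).astype(int)
    return total


def paths_to_idealized(paths: list[ChannelPath]):
    """Exact event list of the summed open-channel count (ground truth).

    Bypasses rendering and threshold detection entirely: the aggregate
    level changes at the union of all per-channel transition times.
    Useful as the dead-time-free reference idealization.
    """
    from .core import IdealizedRecord

    times: list[np.ndarray] = []
    deltas: list[np.ndarray] = []
    for p in paths:
        bounds = np.cumsum(p.durations)[:-1]
        is_open = (p.states == OPEN).astype(int)
        step = np.diff(is_open)
        keep = step != 0
        times.append(bounds[keep])
        deltas.append(step[keep])
    t = np.concatenate(times)
    d = np.concatenate(deltas)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    total = max(p.total_duration for p in paths)
    start_level = sum(int(p.states[0] == OPEN) for p in paths)
    levels = np.concatenate([[start_level], start_level + np.cumsum(d)])
    edges = np.concatenate([[0.0], t, [total]])
    durations = np.diff(edges)
    # drop zero-length events from coincident transitions, merge equal runs
    keep = durations > 0
    levels, durations = levels[keep], durations[keep]
    if levels.size:
        same = np.flatnonzero(levels[1:] == levels[:-1])
        while same.size:
            merged_d = list(durations)
            merged_l = list(levels)
            i = int(same[0])
            merged_d[i] += merged_d[i + 1]
            del merged_d[i + 1], merged_l[i + 1]
            levels = np.asarray(merged_l)
            durations = np.asarray(merged_d)
            same = np.flatnonzero(levels[1:] == levels[:-1])
    return IdealizedRecord(levels.astype(int), durations)


def render_trace(paths: list[ChannelPath], unitary_amplitude: float,
                 sampling_rate: float = DEFAULT_SAMPLING_HZ,
                 noise_sd: float = 0.0,
                 filter_cutoff: float | None = None,
                 seed: int = 0,
                 metadata: dict | None = None) -> Trace:
    """Render channel paths into a sampled current trace.

    Per sample: (number of open channels) x unitary_amplitude, plus
    i.i.d. Gaussian noise of sd `noise_sd`, then an optional zero-phase
    Gaussian low-pass at `filter_cutoff`.
    """
    if filter_cutoff is not None and not filter_cutoff < sampling_rate / 2.0:
        raise ValueError("filter_cutoff must be below the Nyquist frequency")
    duration = max(p.total_duration for p in paths)
    n_samples = int(round(duration * sampling_rate))
    n_open = open_count_per_sample(paths, n_samples, sampling_rate)
    samples = n_open * unitary_amplitude
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, n_samples)
    meta = {"unitary_pA": unitary_amplitude, "noise_sd_pA": noise_sd,
            "n_channels": len(paths), "seed": seed, **(metadata or {})}
    trace = Trace(samples.astype(float), sampling_rate, None, meta)
    if filter_cutoff is not None:
        trace = gaussian_lowpass(trace, filter_cutoff)
    return trace


def generate_assay_series(preset: GeneratorPreset) -> AssaySeries:
    """Synthetic rate-vs-condition table: y = model(x) * (1 + eps),
    eps ~ Normal(0, noise_cv), independently per replicate, clipped at 0."""
    fn = CURVE_MODELS[preset.curve_model]
    x_grid = np.asarray(preset.x_grid, dtype=float)
    x = np.tile(x_grid, preset.n_reps)
    y_true = fn(x, **preset.params)
    rng = np.random.default_rng(preset.seed)
    if preset.noise_cv > 0:
        if preset.noise_mode == "multiplicative":
            y = y_true * (1.0 + rng.normal(0.0, preset.noise_cv, x.size))
        else:
            y = y_true + rng.normal(0.0, preset.noise_cv * float(np.max(np.abs(y_true))), x.size)
        y = np.clip(y, 0.0, None)
    else:
        y = np.asarray(y_true, dtype=float)
    meta = {"preset": preset.name, "curve_model": preset.curve_model,
            "params": dict(preset.params), "noise_cv": preset.noise_cv,
            "n_reps": preset.n_reps, "seed": preset.seed}
    return AssaySeries(x=x, y=y, x_label=preset.x_label, y_label="value",
                       metadata=meta)


def generate_relaxation(amplitude: float, tau: float, baseline: float,
                        duration: float,
                        sampling_rate: float = DEFAULT_SAMPLING_HZ,
                        noise_sd: float = 0.0, seed: int = 0) -> Trace:
    """Single-exponential macroscopic relaxation:
    I(t) = baseline + amplitude * exp(-t/tau) + noise."""
    if not tau > 0:
        raise ValueError("tau must be > 0")
    if not duration > 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    y = baseline + amplitude * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, n)
    meta = {"amplitude_pA": amplitude, "tau_s": tau, "baseline_pA": baseline,
            "seed": seed}
    return Trace(y, sampling_rate, None, meta)


def generate_toy_sequences(seed: int = 0, length: int = 120) -> list[tuple[str, str]]:
    """Synthetic TRPM2-like toy sequences with known embedded motifs.

    Each record embeds the preset's Nudix hexamer plus, where defined,
    its selectivity-filter and post-filter windows, in a random
    background free of spurious near-consensus hexamers.  Window
    coordinates (1-based) are encoded in the record id as
    ``name|nudix=a|filter=b-c|postfilter=d-e`` so downstream callers can
    locate the pore segments without alignment.
    """
    from .presets import SEQUENCE_PRESETS

    # background alphabet excludes E and R to avoid accidental Nudix-like windows
    background = "GSTNQKHPADVLI"
    rng = np.random.default_rng(seed)
    records = []
    for name, spec in SEQUENCE_PRESETS.items():
        seq = list(rng.choice(list(background), size=length))
        pos_nudix = length // 4
        seq[pos_nudix:pos_nudix + 6] = list(spec["nudix"])
        tags = [name, f"nudix={pos_nudix + 1}"]
        if spec["filter"]:
            pos_f = length // 2
            seq[pos_f:pos_f + len(spec["filter"])] = list(spec["filter"])
            tags.append(f"filter={pos_f + 1}-{pos_f + len(spec['filter'])}")
            pos_p = length // 2 + 10
            seq[pos_p:pos_p + len(spec["postfilter"])] = list(spec["postfilter"])
            tags.append(f"postfilter={pos_p + 1}-{pos_p + len(spec['postfilter'])}")
        records.append(("|".join(tags), "".join(seq)))
    return records
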