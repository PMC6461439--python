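"""Three-state Markov gating model for N identical, independent channels.

A single channel gates according to a C_slow <-> O <-> C_fast scheme:
long ("interburst") closures in C_slow, brief ("flickery") closures in
C_fast, and a single open state O, which is the only conducting state.
This is the minimal scheme consistent with a single-exponential open-time
distribution and a bi-exponential closed-time distribution, and produces
the bursting pattern characteristic of TRPM2 currents.

A patch holds N identical independent channels; the observable is only
the number of simultaneously open channels (the conductance level), so
the composite process is an aggregated Markov chain over occupation
vectors (n_slow, n_open, n_fast).  Level-conditional dwell-time densities
are mixtures of exponentials obtained from the within-level block of the
composite generator; rate constants are estimated by maximizing the
dwell-time likelihood over log-rates.

An equivalent C_slow <-> C_fast <-> O ("C-C-O") topology is supported:
the same four rate fields are then read as k_so: Cs->Cf, k_os: Cf->Cs,
k_fo: Cf->O, k_of: O->Cf.  Extracted rates depend on the chosen
topology, but the derived burst and interburst durations do not.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .core import DwellTable

__all__ = [
    "GatingScheme",
    "CompositeModel",
    "GatingFitResult",
    "stationary_distribution",
    "open_probability",
    "compose_channels",
    "level_dwell_pdf",
    "dwell_loglik",
    "fit_gating",
    "burst_stats",
    "channel_count_pvalue",
    "segment_bursts",
]

# single-channel state indices, fixed ordering
C_SLOW, OPEN, C_FAST = 0, 1, 2
STATE_NAMES = ("C_slow", "O", "C_fast")


@dataclass(frozen=True)
class GatingScheme:
    """Four rate constants (s^-1) of the three-state scheme.

    For the default "C-O-C" topology (C_slow <-> O <-> C_fast):
    k_so: C_slow->O opening, k_os: O->C_slow, k_of: O->C_fast flicker
    entry, k_fo: C_fast->O flicker exit.  For "C-C-O"
    (C_slow <-> C_fast <-> O) the fields are read as k_so: Cs->Cf,
    k_os: Cf->Cs, k_fo: Cf->O, k_of: O->Cf.
    """

    k_so: float
    k_os: float
    k_of: float
    k_fo: float
    topology: str = "C-O-C"

    def __post_init__(self) -> None:
        for nm in ("k_so", "k_os", "k_of", "k_fo"):
            if getattr(self, nm) < 0:
                raise ValueError(f"rate {nm} must be >= 0")
        if self.topology not in ("C-O-C", "C-C-O"):
            raise ValueError("topology must be 'C-O-C' or 'C-C-O'")

    def rate_matrix(self) -> np.ndarray:
        """3x3 generator Q over states (C_slow, O, C_fast); rows sum to 0."""
        Q = np.zeros((3, 3))
        if self.topology == "C-O-C":
            Q[C_SLOW, OPEN] = self.k_so
            Q[OPEN, C_SLOW] = self.k_os
            Q[OPEN, C_FAST] = self.k_of
            Q[C_FAST, OPEN] = self.k_fo
        else:  # C-C-O: Cs <-> Cf <-> O
            Q[C_SLOW, C_FAST] = self.k_so
            Q[C_FAST, C_SLOW] = self.k_os
            Q[C_FAST, OPEN] = self.k_fo
            Q[OPEN, C_FAST] = self.k_of
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def rates(self) -> dict[str, float]:
        return {"k_so": self.k_so, "k_os": self.k_os,
                "k_of": self.k_of, "k_fo": self.k_fo}


def stationary_distribution(scheme: GatingScheme) -> np.ndarray:
    """Stationary probabilities pi over (C_slow, O, C_fast), pi Q = 0.

    For the C-O-C topology this has the closed form
    P_o = 1 / (1 + k_os/k_so + k_of/k_fo); the general null-space solve
    is used so both topologies and degenerate (absorbing) schemes with a
    unique stationary state are handled alike.
    """
    Q = scheme.rate_matrix()
    if np.all(Q == 0):
        raise ValueError("all rates are zero: stationary distribution undefined")
    # solve pi Q = 0, sum(pi) = 1 by least squares on the augmented system
    A = np.vstack([Q.T, np.ones(3)])
    b = np.zeros(4)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def open_probability(scheme: GatingScheme) -> float:
    return float(stationary_distribution(scheme)[OPEN])


# ---------------------------------------------------------------------------
# composite (N-channel) model


@dataclass
class CompositeModel:
    """Aggregated generator for N identical independent channels.

    States are occupation vectors (n_slow, n_open, n_fast) with
    n_slow + n_open + n_fast = N; there are (N+1)(N+2)/2 of them.  The
    observable conductance level of a state is n_open.
    """

    scheme: GatingScheme
    n_channels: int
    states: list[tuple[int, int, int]] = field(repr=False)
    generator: np.ndarray = field(repr=False)

    @property
    def levels(self) -> np.ndarray:
        return np.array([s[1] for s in self.states])

    def stationary(self) -> np.ndarray:
        """Composite stationary distribution: multinomial in the
        single-channel stationary probabilities (channels independent)."""
        pi1 = stationary_distribution(self.scheme)
        logpi = np.empty(len(self.states))
        N = self.n_channels
        lp = np.log(np.clip(pi1, 1e-300, None))
        for i, (ns, no, nf) in enumerate(self.states):
            logpi[i] = (gammaln(N + 1) - gammaln(ns + 1) - gammaln(no + 1)
                        - gammaln(nf + 1) + ns * lp[0] + no * lp[1] + nf * lp[2])
        pi = np.exp(logpi)
        return pi / pi.sum()

    def level_distribution(self) -> np.ndarray:
        """Stationary probability of each conductance level 0..N."""
        pi = self.stationary()
        lv = self.levels
        return np.array([pi[lv == l].sum() for l in range(self.n_channels + 1)])


def compose_channels(scheme: GatingScheme, n_channels: int) -> CompositeModel:
    """Build the aggregated generator for N identical independent channels."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    N = n_channels
    states = [(ns, no, N - ns - no) for ns in range(N + 1) for no in range(N + 1 - ns)]
    index = {s: i for i, s in enumerate(states)}
    q1 = scheme.rate_matrix()
    Q = np.zeros((len(states), len(states)))
    for s, i in index.items():
        occ = list(s)
        for a, b in itertools.permutations(range(3), 2):
            if q1[a, b] > 0 and occ[a] > 0:
                dest = list(occ)
                dest[a] -= 1
                dest[b] += 1
                Q[i, index[tuple(dest)]] += occ[a] * q1[a, b]
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return CompositeModel(scheme=scheme, n_channels=N, states=states, generator=Q)


# ---------------------------------------------------------------------------
# level-conditional dwell densities


def _level_mixture(model: CompositeModel, level: int):
    """Exponential-mixture representation of the level-`level` dwell pdf.

    Returns (weights c_i, eigenvalues lam_i) such that
    f(t) = sum_i c_i * exp(lam_i * t).  The number of components equals
    the size of the level class, N - level + 1.
    """
    if not 0 <= level <= model.n_channels:
        raise ValueError(f"level {level} outside [0, {model.n_channels}]")
    lv = model.levels
    inside = np.flatnonzero(lv == level)
    outside = np.flatnonzero(lv != level)
    Q = model.generator
    Qll = Q[np.ix_(inside, inside)]
    pi = model.stationary()
    # stationary entry flux into the class
    flux = pi[outside] @ Q[np.ix_(outside, inside)]
    total = flux.sum()
    if not total > 0:
        raise ValueError(f"level {level} is never entered under this scheme")
    phi = flux / total
    exit_rates = -Qll @ np.ones(len(inside))
    lam, V = np.linalg.eig(Qll)
    c = (phi @ V) * (np.linalg.solve(V, exit_rates))
    # chain is reversible-like here; eigensystem is real up to roundoff
    return np.real(c), np.real(lam)


def level_dwell_pdf(model: CompositeModel, level: int, t) -> np.ndarray:
    """Dwell-time density at a conductance level, evaluated at times t (s).

    f_l(t) = phi_l exp(Q_ll t) q_exit, with phi_l the stationary-flux
    entry vector over the level's states.  Integrates to 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("dwell times must be > 0")
    c, lam = _level_mixture(model, level)
    vals = np.sum(c[None, :] * np.exp(np.outer(t, lam)), axis=1)
    return np.clip(vals, 0.0, None)


def dwell_loglik(model: CompositeModel, dwells: DwellTable) -> float:
    """Log-likelihood of a dwell table, dwells treated as independent
    draws from their level-conditional densities."""
    total = 0.0
    for level, times in dwells.dwells.items():
        if times.size == 0:
            continue
        if level > model.n_channels:
            raise ValueError(
                f"dwell level {level} exceeds model channel count {model.n_channels}")
        if np.any(times <= 0):
            raise ValueError("dwell durations must be > 0")
        c, lam = _level_mixture(model, level)
        # evaluate sum_i c_i exp(lam_i t) stably: lam_i <= 0
        vals = np.sum(c[None, :] * np.exp(np.outer(times, lam)), axis=1)
        vals = np.clip(vals, 1e-300, None)
        total += float(np.sum(np.log(vals)))
    return total


# ---------------------------------------------------------------------------
# burst statistics and channel-count test


def burst_stats(scheme: GatingScheme) -> dict[str, float]:
    """Burst-level summary statistics from the rate constants.

    Bursts are sojourns in {O, C_fast} delimited by C_slow visits
    (C-O-C), or runs of openings uninterrupted by a C_slow visit
    (C-C-O).  For C-O-C:

        tau_b  = (1/k_os) * (1 + k_of/k_fo)
        tau_ib = 1/k_so
        mean_open_time    = 1/(k_os + k_of)
        openings_per_burst = 1 + k_of/k_os
    """
    s = scheme
    if s.topology == "C-O-C":
        if s.k_os <= 0 or s.k_so <= 0:
            raise ValueError("k_os and k_so must be > 0 for finite burst statistics")
        if s.k_fo == 0 and s.k_of > 0:
            raise ValueError("k_fo = 0 with k_of > 0: flicker state absorbing, bursts infinite")
        tau_b = (1.0 / s.k_os) * (1.0 + (s.k_of / s.k_fo if s.k_of > 0 else 0.0))
        tau_ib = 1.0 / s.k_so
        mean_open = 1.0 / (s.k_os + s.k_of)
        opb = 1.0 + s.k_of / s.k_os
    else:
        # C-C-O: Cs <-(k_os)- Cf -(k_fo)-> O, Cs -(k_so)-> Cf, O -(k_of)-> Cf
        if s.k_os <= 0 or s.k_so <= 0 or s.k_of <= 0 or s.k_fo <= 0:
            raise ValueError("all four rates must be > 0 for C-C-O burst statistics")
        b, c, d, a = s.k_os, s.k_fo, s.k_of, s.k_so
        opb = (b + c) / b
        mean_open = 1.0 / d
        # openings plus intra-burst flicker visits to C_fast
        tau_b = opb / d + (opb - 1.0) / (b + c)
        # burst-terminating C_fast sojourn + first passage Cs -> O
        t_f = (1.0 + b / a) / c
        tau_ib = 1.0 / (b + c) + 1.0 / a + t_f
    return {
        "P_o": open_probability(s),
        "tau_b": tau_b,
        "tau_ib": tau_ib,
        "mean_open_time": mean_open,
        "openings_per_burst": opb,
    }


def channel_count_pvalue(t_top: float, tau_ib: float) -> float:
    """Probability that a hypothetical extra channel, opening at rate
    1/tau_ib, never opens during the cumulative time `t_top` spent with
    all N' observed channels open: p = exp(-t_top/tau_ib).

    Callers compare against 0.001 to exclude N > N' with high
    confidence.
    """
    if t_top < 0:
        raise ValueError("t_top must be >= 0")
    if not tau_ib > 0:
        raise ValueError("tau_ib must be > 0")
    return math.exp(-t_top / tau_ib)


def segment_bursts(states: np.ndarray, durations: np.ndarray,
                   topology: str = "C-O-C") -> dict[str, np.ndarray]:
    """Segment a true single-channel state path into bursts.

    A burst runs from an entry into O until the next visit to C_slow;
    intra-burst C_fast sojourns count toward the burst.  The interburst
    gap is the closed time separating consecutive bursts (it contains
    the C_slow sojourn(s) plus, for C-C-O, the traversed C_fast time).
    Edge (censored) bursts and gaps are dropped.
    """
    states = np.asarray(states)
    durations = np.asarray(durations, dtype=float)
    open_idx = np.flatnonzero(states == OPEN)
    if open_idx.size < 2:
        return {"burst": np.empty(0), "interburst": np.empty(0)}
    bursts: list[float] = []
    gaps: list[float] = []
    cur = durations[open_idx[0]]
    for a, b in zip(open_idx[:-1], open_idx[1:]):
        closed = durations[a + 1:b]
        splits = bool(np.any(states[a + 1:b] == C_SLOW))
        if splits:
            bursts.append(cur)
            gaps.append(float(closed.sum()))
            cur = durations[b]
        else:
            cur += float(closed.sum()) + durations[b]
    bursts.append(cur)
    # first and last bursts are censored by the record edges; interior
    # gaps are fully observed (bounded by openings on both sides).
    return {"burst": np.asarray(bursts[1:-1]), "interburst": np.asarray(gaps)}


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass
class GatingFitResult:
    rates: GatingScheme
    log_likelihood: float
    std_errors: dict[str, float]
    P_o: float
    tau_b: float
    tau_ib: float
    n_channels: int
    convergence: str  # "converged" | "max-iterations" | "failed"
    n_dwells: int = 0
    message: str = ""


def _auto_inits(dwells: DwellTable, N: int, topology: str,
                n_starts: int, seed: int) -> list[np.ndarray]:
    """Starting points (log10 rates) for the multi-start optimization.

    One start is moment-based: the top-level dwell mean pins
    k_os + k_of (top-level exit rate is N'(k_os+k_of)), closed dwells
    are split at a fixed boundary into flickery and interburst
    populations to apportion the remaining rates.  Additional starts are
    log-uniform draws around physiologically plausible scales (bursts of
    order seconds, flickers of order milliseconds).
    """
    rng = np.random.default_rng(seed)
    top = dwells.max_level
    inits = []
    top_d = dwells.dwells.get(top, np.empty(0))
    all_closed = np.concatenate(
        [v for l, v in dwells.dwells.items() if l < top and v.size] or [np.empty(0)])
    if top_d.size >= 5 and all_closed.size >= 5:
        exit_open = 1.0 / (max(top, 1) * float(np.mean(top_d)))
        split = 0.02  # s, boundary between flicker and interburst closures
        brief = all_closed[all_closed < split]
        long_ = all_closed[all_closed >= split]
        k_fo = 1.0 / float(np.mean(brief)) if brief.size else 300.0
        k_so = 1.0 / float(np.mean(long_)) if long_.size else 0.5
        frac_brief = brief.size / all_closed.size
        k_of = exit_open * frac_brief
        k_os = max(exit_open - k_of, 0.05 * exit_open)
        k_of = max(k_of, 0.05 * exit_open)
        inits.append(np.log10([k_so, k_os, k_of, k_fo]))
    lo = np.log10([0.05, 0.05, 0.3, 30.0])
    hi = np.log10([5.0, 5.0, 30.0, 3000.0])
    while len(inits) < n_starts:
        inits.append(rng.uniform(lo, hi))
    return inits


def fit_gating(dwells: DwellTable, n_channels: int,
               init: GatingScheme | None = None,
               topology: str = "C-O-C",
               n_starts: int = 5, seed: int = 0) -> GatingFitResult:
    """Maximum-likelihood fit of the three-state scheme to a dwell table.

    Optimizes the dwell-time log-likelihood over the four log-rates with
    a multi-start Nelder-Mead search; standard errors come from the
    finite-difference Hessian at the optimum (delta method back to the
    natural scale).
    """
    if n_channels < dwells.max_level:
        raise ValueError(
            f"n_channels ({n_channels}) < maximum observed level ({dwells.max_level})")
    n_open_dwells = sum(v.size for l, v in dwells.dwells.items() if l > 0)
    if n_open_dwells == 0:
        return GatingFitResult(
            rates=GatingScheme(0, 0, 0, 0), log_likelihood=float("nan"),
            std_errors={}, P_o=float("nan"), tau_b=float("nan"),
            tau_ib=float("nan"), n_channels=n_channels, convergence="failed",
            n_dwells=dwells.n_dwells, message="no openings: rates unidentifiable")
    if dwells.n_dwells < 50:
        import warnings
        warnings.warn(f"only {dwells.n_dwells} dwells; rate estimates will be noisy")

    def nll(logq: np.ndarray) -> float:
        rates = 10.0 ** np.asarray(logq)
        if np.any(rates > 1e7) or np.any(rates < 1e-7):
            return 1e12
        scheme = GatingScheme(*rates, topology=topology)
        model = compose_channels(scheme, n_channels)
        try:
            return -dwell_loglik(model, dwells)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    starts = _auto_inits(dwells, n_channels, topology, n_starts, seed)
    if init is not None:
        starts.insert(0, np.log10([max(r, 1e-6) for r in
                                   (init.k_so, init.k_os, init.k_of, init.k_fo)]))
    best = None
    for x0 in starts:
        sol = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        if best is None or sol.fun < best.fun:
            best = sol
    rates = 10.0 ** best.x
    scheme = GatingScheme(*rates, topology=topology)
    stats = burst_stats(scheme)
    se = _hessian_std_errors(nll, best.x, rates)
    convergence = "converged" if best.success else "max-iterations"
    return GatingFitResult(
        rates=scheme, log_likelihood=-float(best.fun), std_errors=se,
        P_o=stats["P_o"], tau_b=stats["tau_b"], tau_ib=stats["tau_ib"],
        n_channels=n_channels, convergence=convergence,
        n_dwells=dwells.n_dwells)


def _hessian_std_errors(nll, x_opt: np.ndarray, rates: np.ndarray,
                        h: float = 1e-3) -> dict[str, float]:
    """Observed-information standard errors for the four rates."""
    n = len(x_opt)
    H = np.zeros((n, n))
    f0 = nll(x_opt)
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(n)[i] * h
            ej = np.eye(n)[j] * h
            if i == j:
                H[i, i] = (nll(x_opt + ei) - 2 * f0 + nll(x_opt - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll(x_opt + ei + ej) - nll(x_opt + ei - ej)
                    - nll(x_opt - ei + ej) + nll(x_opt - ei - ej)) / (4 * h ** 2)
    names = ("k_so", "k_os", "k_of", "k_fo")
    try:
        cov = np.linalg.inv(H)
        diag = np.clip(np.diag(cov), 0, None)
        se_log = np.sqrt(diag)
        return {nm: float(se * r * np.log(10))
                for nm, se, r in zip(names, se_log, rates)}
    except np.linalg.LinAlgError:
        return {nm: float("inf") for nm in names}
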