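"""Coupled-phosphatase ADPRase assay model and enzyme-kinetic curve fits.

The assay reads out ADPR hydrolysis as inorganic phosphate (Pi) liberated
by co-applied alkaline phosphatase from both reaction products (AMP and
ribose-5-phosphate), so 2 mol Pi are released per mol ADPR hydrolyzed.
AMP controls yield 1 Pi per AMP; the non-hydrolyzable analog AMPCPR
yields none.  Turnover numbers are computed per subunit:

    k_cat = (Pi / stoichiometry) / ([enzyme] * t)

Curve models fitted here: Michaelis-Menten, Hill, a compound double-Hill
describing high- plus low-affinity Mg2+ activation,

    kcat(x) = (kcat1*K2^n2*x^n1 + kcat2*x^(n1+n2))
              / (K1^n1*K2^n2 + K2^n2*x^n1 + x^(n1+n2)),

and a single-group pH titration kcat = kcat_max / (1 + 10^(pKa - pH)).
Fits are unweighted least squares on untransformed rates; positive
parameters are optimized in log-space so they can never change sign, and
standard errors come from the Jacobian-based covariance at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .core import AssaySeries

__all__ = [
    "STOICHIOMETRY",
    "EnzymeFitResult",
    "NetPi",
    "released_pi",
    "compute_kcat",
    "subtract_background",
    "normalize_to_max",
    "estimate_quantitation_floor",
    "michaelis_menten",
    "hill",
    "double_hill",
    "ph_titration",
    "CURVE_MODELS",
    "fit_michaelis_menten",
    "fit_hill",
    "fit_double_hill",
    "fit_ph_titration",
]

# moles of Pi liberated by alkaline phosphatase per mole of substrate
# turned over: ADPR -> AMP + R5P (2 Pi), AMP -> adenosine + Pi (1),
# AMPCPR is resistant to hydrolysis (0).
STOICHIOMETRY: dict[str, float] = {"ADPR": 2.0, "AMP": 1.0, "AMPCPR": 0.0}


# ---------------------------------------------------------------------------
# assay arithmetic


def released_pi(substrate: str, hydrolyzed_conc: float) -> float:
    """Pi (uM) liberated when `hydrolyzed_conc` (uM) of substrate is turned over."""
    if substrate not in STOICHIOMETRY:
        raise ValueError(f"unknown substrate {substrate!r}; expected one of {sorted(STOICHIOMETRY)}")
    if hydrolyzed_conc < 0:
        raise ValueError("hydrolyzed_conc must be >= 0")
    return STOICHIOMETRY[substrate] * hydrolyzed_conc


def compute_kcat(pi_released: float, protein_conc: float, incubation: float,
                 substrate: str = "ADPR") -> float:
    """Per-subunit turnover rate (s^-1) from liberated Pi.

    Parameters: pi_released in uM, protein_conc in nM (subunit
    concentration for tetramers), incubation in s.
    """
    if substrate not in STOICHIOMETRY:
        raise ValueError(f"unknown substrate {substrate!r}")
    if not protein_conc > 0:
        raise ValueError("protein_conc must be > 0 (division by zero otherwise)")
    if not incubation > 0:
        raise ValueError("incubation must be > 0")
    stoich = STOICHIOMETRY[substrate]
    if stoich == 0:
        raise ValueError(f"{substrate} releases no Pi; kcat undefined")
    hydrolyzed_um = pi_released / stoich
    protein_um = protein_conc * 1e-3
    return hydrolyzed_um / (protein_um * incubation)


class NetPi(NamedTuple):
    value: float
    flag: str  # "ok" | "at-background" | "below-background"


def subtract_background(sample_pi: float, background_pi: float) -> NetPi:
    """Net Pi after removing the spontaneous-hydrolysis background.

    A net of exactly zero is flagged "at-background"; negative nets are
    returned as-is but flagged "below-background" (signal
    indistinguishable from background).
    """
    if sample_pi < 0 or background_pi < 0:
        raise ValueError("Pi amounts must be >= 0")
    net = sample_pi - background_pi
    if net < 0:
        return NetPi(net, "below-background")
    if net == 0:
        return NetPi(net, "at-background")
    return NetPi(net, "ok")


def normalize_to_max(series: AssaySeries) -> AssaySeries:
    """Divide all values by the (replicate-mean) value at the highest condition."""
    x_top = series.x.max()
    top = float(np.mean(series.y[series.x == x_top]))
    if not top > 0:
        raise ValueError("value at the maximal condition must be > 0")
    return AssaySeries(
        x=series.x.copy(),
        y=series.y / top,
        x_label=series.x_label,
        y_label=series.y_label,
        normalized=True,
        metadata={**series.metadata, "normalization_factor": top},
    )


def estimate_quantitation_floor(protein_conc: float, incubation: float,
                                pi_detection_limit: float) -> float:
    """Smallest resolvable kcat (s^-1): the turnover whose released Pi
    just reaches the colorimetric detection limit at the given enzyme
    concentration (nM) and incubation time (s)."""
    if not pi_detection_limit > 0:
        raise ValueError("pi_detection_limit must be > 0")
    return compute_kcat(pi_detection_limit, protein_conc, incubation, "ADPR")


# ---------------------------------------------------------------------------
# curve models


def michaelis_menten(x, v_max, k_m):
    x = np.asarray(x, dtype=float)
    return v_max * x / (k_m + x)


def hill(x, y_max, k_half, n_h):
    x = np.asarray(x, dtype=float)
    xn = np.power(x, n_h)
    return y_max * xn / (np.power(k_half, n_h) + xn)


def double_hill(x, k_cat1, k_cat2, k_1, k_2, n_1, n_2):
    """Compound two-site activation curve (high- and low-affinity Mg2+ sites)."""
    x = np.asarray(x, dtype=float)
    xn1 = np.power(x, n_1)
    xn12 = np.power(x, n_1 + n_2)
    k2n2 = np.power(k_2, n_2)
    k1n1 = np.power(k_1, n_1)
    num = k_cat1 * k2n2 * xn1 + k_cat2 * xn12
    den = k1n1 * k2n2 + k2n2 * xn1 + xn12
    return num / den


def ph_titration(ph, k_cat_max, pka):
    ph = np.asarray(ph, dtype=float)
    return k_cat_max / (1.0 + np.power(10.0, pka - ph))


CURVE_MODELS: dict[str, Callable] = {
    "michaelis_menten": michaelis_menten,
    "hill": hill,
    "double_hill": double_hill,
    "ph_titration": ph_titration,
    "dose_response": hill,
}


# ---------------------------------------------------------------------------
# fitting engine


@dataclass
class EnzymeFitResult:
    """Outcome of a kinetic curve fit.

    ``status`` is "ok", "warning" (fit usable but flagged, see
    ``message``) or "failed" (parameters are not meaningful).
    """

    model: str
    params: dict[str, float] = field(default_factory=dict)
    std_errors: dict[str, float] = field(default_factory=dict)
    residual_sum_sq: float = float("nan")
    n_points: int = 0
    status: str = "ok"
    message: str = ""

    def predict(self, x):
        fn = CURVE_MODELS[self.model]
        return fn(x, **self.params)


def _fit_curve(model: str, x: np.ndarray, y: np.ndarray,
               param_names: list[str], p0: list[float],
               log_params: set[str]) -> EnzymeFitResult:
    """Least-squares fit; parameters listed in `log_params` are optimized
    as log10 so they remain strictly positive."""

    def pack(p):
        return [np.log10(v) if nm in log_params else v for nm, v in zip(param_names, p)]

    def unpack(q):
        return [10.0 ** v if nm in log_params else v for nm, v in zip(param_names, q)]

    fn = CURVE_MODELS[model]

    def resid(q):
        return fn(x, *unpack(q)) - y

    try:
        sol = least_squares(resid, pack(p0), method="lm", max_nfev=20000)
    except Exception as exc:  # singular starting point etc.
        return EnzymeFitResult(model=model, n_points=x.size, status="failed",
                               message=f"optimizer error: {exc}")
    if not sol.success:
        return EnzymeFitResult(model=model, n_points=x.size, status="failed",
                               message=sol.message)
    vals = unpack(sol.x)
    params = dict(zip(param_names, (float(v) for v in vals)))
    ssr = float(np.sum(sol.fun ** 2))
    dof = max(x.size - len(param_names), 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * ssr / dof
        se_q = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_q = np.full(len(param_names), np.inf)
    # delta method back to natural scale for log10-fitted parameters
    std = {}
    for nm, v, se in zip(param_names, vals, se_q):
        std[nm] = float(se * v * np.log(10)) if nm in log_params else float(se)
    return EnzymeFitResult(model=model, params=params, std_errors=std,
                           residual_sum_sq=ssr, n_points=int(x.size))


def _series_xy(series: AssaySeries) -> tuple[np.ndarray, np.ndarray]:
    return series.x, series.y


def fit_michaelis_menten(series: AssaySeries) -> EnzymeFitResult:
    """Fit v = V_max*S / (K_M + S).  Needs >= 3 distinct concentrations."""
    x, y = _series_xy(series)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")
    if np.ptp(y) <= 1e-12 * max(1.0, abs(float(np.max(y)))):
        return EnzymeFitResult(model="michaelis_menten", n_points=x.size,
                               status="failed", message="constant response: K_M unidentifiable")
    v0 = float(np.max(y))
    k0 = _x_at_half(x, y, v0)
    res = _fit_curve("michaelis_menten", x, y, ["v_max", "k_m"], [v0, k0],
                     log_params={"v_max", "k_m"})
    return res


def fit_hill(series: AssaySeries, fix_n: float | None = None) -> EnzymeFitResult:
    """Fit y = y_max * x^n / (K_half^n + x^n).

    `fix_n` pins the Hill coefficient (fix_n=1 reproduces the
    Michaelis-Menten fit on the same data).
    """
    x, y = _series_xy(series)
    if np.unique(x).size < 4 and fix_n is None:
        raise ValueError("need >= 4 distinct x values for a free Hill fit")
    if np.ptp(y) <= 1e-12 * max(1.0, abs(float(np.max(y)))):
        return EnzymeFitResult(model="hill", n_points=x.size,
                               status="failed", message="constant response")
    y0 = float(np.max(y))
    k0 = _x_at_half(x, y, y0)
    if fix_n is not None:

        def resid(q):
            return hill(x, 10.0 ** q[0], 10.0 ** q[1], fix_n) - y

        sol = least_squares(resid, [np.log10(y0), np.log10(k0)], method="lm")
        params = {"y_max": float(10.0 ** sol.x[0]), "k_half": float(10.0 ** sol.x[1]),
                  "n_h": float(fix_n)}
        return EnzymeFitResult(model="hill", params=params,
                               residual_sum_sq=float(np.sum(sol.fun ** 2)),
                               n_points=int(x.size),
                               status="ok" if sol.success else "failed",
                               message="" if sol.success else sol.message)
    return _fit_curve("hill", x, y, ["y_max", "k_half", "n_h"], [y0, k0, 1.0],
                      log_params={"y_max", "k_half", "n_h"})


def fit_double_hill(series: AssaySeries) -> EnzymeFitResult:
    """Fit the compound double-Hill activation curve (6 parameters).

    Requires >= 7 distinct x spanning both transitions; returns a failed
    status when the sampled range does not bracket the high-affinity
    constant K_1.
    """
    x, y = _series_xy(series)
    if np.unique(x).size < 7:
        raise ValueError("need >= 7 distinct x values for a double-Hill fit")
    y_top = float(np.max(y))
    # initial guesses: first plateau from the low-x shoulder, K's from
    # half-crossings; Hill slopes start at (2, 1).
    k1_0 = _x_at_half(x, y, y_top * 0.5)
    k2_0 = max(_x_at_half(x, y, y_top), 10.0 * k1_0)
    kcat1_0 = max(y_top * 0.5, 1e-9)
    p0 = [kcat1_0, y_top, k1_0, k2_0, 2.0, 1.0]
    names = ["k_cat1", "k_cat2", "k_1", "k_2", "n_1", "n_2"]
    res = _fit_curve("double_hill", x, y, names, p0, log_params=set(names))
    if res.status == "ok" and not (x.min() < res.params["k_1"] < x.max()):
        res.status = "failed"
        res.message = "x range does not span K_1: high-affinity site unidentifiable"
    return res


def fit_ph_titration(series: AssaySeries) -> EnzymeFitResult:
    """Fit kcat = kcat_max / (1 + 10^(pKa - pH)).

    When the sampled pH range lies entirely on one side of the fitted
    midpoint the result is flagged "warning" and standard errors are
    inflated, because the plateau and midpoint are then nearly collinear.
    """
    x, y = _series_xy(series)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct pH values")
    y0 = float(np.max(y))
    pka0 = _x_at_half(x, y, y0)
    res = _fit_curve("ph_titration", x, y, ["k_cat_max", "pka"], [y0, pka0],
                     log_params={"k_cat_max"})
    if res.status == "ok":
        pka = res.params["pka"]
        if not (x.min() < pka < x.max()):
            res.status = "warning"
            res.message = "pH range does not bracket the fitted pKa"
            res.std_errors = {k: v * 10.0 for k, v in res.std_errors.items()}
    return res


def _x_at_half(x: np.ndarray, y: np.ndarray, y_top: float) -> float:
    """x value whose response is closest to half of y_top (positive)."""
    idx = int(np.argmin(np.abs(y - 0.5 * y_top)))
    val = float(x[idx])
    if val <= 0:
        pos = x[x > 0]
        val = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    return val
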