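"""Named parameter presets for the synthetic generators.

Each preset fixes the generating parameters of one study condition:
enzyme-kinetic curve parameters (Michaelis-Menten, Hill, double-Hill,
pH-titration, ADPR dose-response), macroscopic relaxation time
constants, single-channel gating rate constants, and unitary current
amplitudes.  Presets are the package's reference conditions; generators
accept them by name or as explicit parameter dictionaries.
"""

from __future__ import annotations

import numpy as np

from .gating import GatingScheme

__all__ = [
    "ENZYME_PRESETS",
    "RELAXATION_PRESETS",
    "GATING_SCHEMES",
    "UNITARY_AMPLITUDES",
    "SEQUENCE_PRESETS",
]


def _log_grid(lo: float, hi: float, n: int) -> list[float]:
    return list(np.geomspace(lo, hi, n))


# Enzyme-assay curve presets.  x units: uM ADPR for michaelis_menten and
# dose_response, mM free Mg2+ for hill/double_hill, pH units for
# ph_titration.  Rates in s^-1 (per subunit); normalized curves are
# dimensionless with v_max/y_max = 1.
ENZYME_PRESETS: dict[str, dict] = {
    # ADPR saturation of hydrolysis rate, normalized to the top concentration
    "mm_nv_full": {
        "curve_model": "michaelis_menten",
        "params": {"v_max": 1.0, "k_m": 18.0},
        "x_grid": _log_grid(10.0, 300.0, 6),
        "x_label": "adpr_um",
    },
    "mm_nv_domain": {
        "curve_model": "michaelis_menten",
        "params": {"v_max": 1.0, "k_m": 7.7},
        "x_grid": _log_grid(5.0, 320.0, 7),
        "x_label": "adpr_um",
    },
    "mm_sr_domain": {
        "curve_model": "michaelis_menten",
        "params": {"v_max": 1.0, "k_m": 5.9},
        "x_grid": _log_grid(5.0, 320.0, 7),
        "x_label": "adpr_um",
    },
    # Mg2+ activation of turnover at fixed pH (single Hill, n ~ 2)
    "hill_mg_ph85": {
        "curve_model": "hill",
        "params": {"y_max": 43.9, "k_half": 1.6, "n_h": 2.0},
        "x_grid": _log_grid(0.1, 30.0, 8),
        "x_label": "mg_mm",
    },
    "hill_mg_ph57": {
        "curve_model": "hill",
        "params": {"y_max": 3.5, "k_half": 10.8, "n_h": 2.0},
        "x_grid": _log_grid(0.3, 100.0, 8),
        "x_label": "mg_mm",
    },
    # pH titration of turnover at fixed high Mg2+
    "ph_titration_high_mg": {
        "curve_model": "ph_titration",
        "params": {"k_cat_max": 40.0, "pka": 6.8},
        "x_grid": [5.7, 6.4, 7.1, 7.8, 8.5],
        "x_label": "ph",
    },
    # two-site Mg2+ activation (high-affinity pair + low-affinity third ion)
    "double_hill_sr_ph85": {
        "curve_model": "double_hill",
        "params": {"k_cat1": 1.57, "k_cat2": 3.59, "k_1": 0.031,
                   "k_2": 29.0, "n_1": 2.8, "n_2": 0.86},
        "x_grid": _log_grid(0.003, 300.0, 20),
        "x_label": "mg_mm",
    },
    "double_hill_sr_ph71": {
        "curve_model": "double_hill",
        "params": {"k_cat1": 1.76, "k_cat2": 3.44, "k_1": 0.102,
                   "k_2": 35.0, "n_1": 1.8, "n_2": 1.0},
        "x_grid": _log_grid(0.003, 300.0, 20),
        "x_label": "mg_mm",
    },
    # macroscopic current activation by ADPR (fractional current)
    "dose_response_adpr": {
        "curve_model": "dose_response",
        "params": {"y_max": 1.0, "k_half": 2.0, "n_h": 1.5},
        "x_grid": [0.3, 1.0, 3.0, 10.0, 30.0, 100.0],
        "x_label": "adpr_um",
    },
}

# Macroscopic relaxation presets: (amplitude pA, tau s, baseline pA).
RELAXATION_PRESETS: dict[str, dict] = {
    # slow inactivation of the zebrafish channel in maintained ligand
    "inactivation_dr": {"amplitude": -500.0, "tau": 655.0, "baseline": 0.0},
    # fast inactivation of the human channel
    "inactivation_hs": {"amplitude": -500.0, "tau": 29.0, "baseline": 0.0},
    # deactivation upon ADPR removal (time constant ~100 ms)
    "deactivation_nv": {"amplitude": -200.0, "tau": 0.1, "baseline": 0.0},
}

# Single-channel gating rates (s^-1).  The wild-type-like scheme gives
# P_o ~ 0.5, mean burst and interburst durations ~ 1.5 s, and ~2 ms
# flickery closures.
GATING_SCHEMES: dict[str, GatingScheme] = {
    "nv_wt": GatingScheme(k_so=0.67, k_os=0.67, k_of=2.68, k_fo=500.0),
}

# Unitary current amplitude at -20 mV (pA): Na+ current through the open
# pore is partially blocked by cytosolic Mg2+.
UNITARY_AMPLITUDES: dict[str, float] = {
    "with_mg": -2.5,
    "mg_free": -4.0,
}

# Toy protein presets for the motif scanner: Nudix hexamer plus pore
# windows (selectivity filter segment; post-filter prefix + triplet).
# Sequences built from these are synthetic stand-ins, not real orthologs.
SEQUENCE_PRESETS: dict[str, dict] = {
    "toy_invertebrate_nv": {"nudix": "AEFGEE", "filter": "FGE",
                            "postfilter": "FDES"},
    "toy_invertebrate_sr": {"nudix": "REFMEE", "filter": "FGE",
                            "postfilter": "FEDT"},
    "toy_soluble_adprase": {"nudix": "REFGEE", "filter": "",
                            "postfilter": ""},
    "toy_vertebrate_hs": {"nudix": "RILRQE", "filter": "FGQ",
                          "postfilter": "PSAN"},
    "toy_mutant_il": {"nudix": "AILGEE", "filter": "FGE",
                      "postfilter": "FDES"},
    "toy_mutant_kk": {"nudix": "AEFGKK", "filter": "FGE",
                      "postfilter": "FDES"},
}
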