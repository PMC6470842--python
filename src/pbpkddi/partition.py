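"""Tissue-to-plasma partition prediction for ionised bases (Rodgers-Rowland).

Optional utility: the shipped default parameter registry overrides these
predictions with measured/derived values wherever those exist, and uses the
prediction only for tissues with no measured steady-state ratio (adipose,
bone, gut, muscle, skin).

The method partitions a moderate-to-strong monoprotic base between tissue
water (with pH-driven ion trapping), neutral lipid/phospholipid, and acidic
phospholipid; the acidic-phospholipid association constant is calibrated
from red-blood-cell partitioning implied by the blood-to-plasma ratio.
"""

from __future__ import annotations

import math

__all__ = ["predict_kp_rodgers_rowland", "RAT_TISSUE_COMPOSITION"]

# Fractional tissue composition of the rat: extracellular water, intracellular
# water, neutral lipid, neutral phospholipid (v/v), and acidic phospholipid
# concentration (mg/g tissue). Standard literature values.
RAT_TISSUE_COMPOSITION: dict[str, dict[str, float]] = {
    #            f_EW    f_IW    f_NL     f_NP     AP
    "adipose": {"f_ew": 0.135, "f_iw": 0.017, "f_nl": 0.853, "f_np": 0.0016, "ap": 0.40},
    "bone":    {"f_ew": 0.100, "f_iw": 0.346, "f_nl": 0.017, "f_np": 0.0017, "ap": 0.67},
    "brain":   {"f_ew": 0.162, "f_iw": 0.620, "f_nl": 0.039, "f_np": 0.0015, "ap": 0.40},
    "gut":     {"f_ew": 0.282, "f_iw": 0.475, "f_nl": 0.038, "f_np": 0.0125, "ap": 2.41},
    "heart":   {"f_ew": 0.320, "f_iw": 0.456, "f_nl": 0.014, "f_np": 0.0111, "ap": 2.25},
    "kidney":  {"f_ew": 0.273, "f_iw": 0.483, "f_nl": 0.012, "f_np": 0.0240, "ap": 5.03},
    "liver":   {"f_ew": 0.161, "f_iw": 0.573, "f_nl": 0.014, "f_np": 0.0240, "ap": 4.56},
    "lung":    {"f_ew": 0.336, "f_iw": 0.446, "f_nl": 0.022, "f_np": 0.0128, "ap": 3.91},
    "muscle":  {"f_ew": 0.118, "f_iw": 0.630, "f_nl": 0.010, "f_np": 0.0072, "ap": 1.53},
    "skin":    {"f_ew": 0.382, "f_iw": 0.291, "f_nl": 0.060, "f_np": 0.0044, "ap": 1.32},
    "spleen":  {"f_ew": 0.207, "f_iw": 0.579, "f_nl": 0.0077, "f_np": 0.0113, "ap": 3.18},
}

# Red blood cell composition and pH landscape.
_RBC = {"f_iw": 0.603, "f_nl": 0.0017, "f_np": 0.0029, "ap": 0.5}
_PH_PLASMA = 7.4
_PH_IW = 7.0     # tissue-cell intracellular water
_PH_RBC = 7.22   # red-blood-cell intracellular water
_HEMATOCRIT = 0.46


def _lipid_term(P: float, f_nl: float, f_np: float, ion_p: float) -> float:
    return (P * f_nl + (0.3 * P + 0.7) * f_np) / (1.0 + ion_p)


def predict_kp_rodgers_rowland(
        pKa: float, logP: float, fup: float, R: float = 1.0,
        composition: dict[str, dict[str, float]] | None = None,
        hematocrit: float = _HEMATOCRIT,
) -> tuple[dict[str, float], dict[str, float]]:
    """Predict equilibrium tissue-to-plasma partition coefficients (Kp) and
    tissue unbound fractions for a monoprotic base.

    Returns ``(Kp_by_tissue, fu_by_tissue)`` where ``fu = 1 / Kpu`` (the
    tissue-to-plasma-water partition), the approximation under which the
    passive tissue-to-plasma ratio is ``fup / fu_tissue``.
    """
    if composition is None:
        composition = RAT_TISSUE_COMPOSITION
    missing = [t for t, c in composition.items()
               if not {"f_ew", "f_iw", "f_nl", "f_np", "ap"} <= set(c)]
    if missing:
        raise ValueError(f"incomplete composition entries for {missing}")
    if not (0 < fup <= 1):
        raise ValueError("fup must be in (0, 1]")

    P = 10.0 ** logP
    ion_p = 10.0 ** (pKa - _PH_PLASMA)
    ion_iw = 10.0 ** (pKa - _PH_IW)
    ion_rbc = 10.0 ** (pKa - _PH_RBC)

    # acidic-phospholipid association constant from RBC partitioning
    kpu_bc = (R - (1.0 - hematocrit)) / (hematocrit * fup)
    water_bc = _RBC["f_iw"] * (1.0 + ion_rbc) / (1.0 + ion_p)
    lipid_bc = _lipid_term(P, _RBC["f_nl"], _RBC["f_np"], ion_p)
    ka_ap = ((kpu_bc - water_bc - lipid_bc) * (1.0 + ion_p)
             / (_RBC["ap"] * ion_rbc))
    ka_ap = max(ka_ap, 0.0)  # a base with no measurable cell binding

    kp: dict[str, float] = {}
    fu: dict[str, float] = {}
    for tissue, c in composition.items():
        kpu = (c["f_ew"]
               + c["f_iw"] * (1.0 + ion_iw) / (1.0 + ion_p)
               + ka_ap * c["ap"] * ion_iw / (1.0 + ion_p)
               + _lipid_term(P, c["f_nl"], c["f_np"], ion_p))
        kp[tissue] = kpu * fup
        fu[tissue] = 1.0 / kpu
    return kp, fu
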