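"""Algebraic parameter derivations: from observed clearances, steady-state
tissue ratios and in-vitro rates to the mechanistic model inputs.

All operations are closed-form and unit-preserving: clearances keep the basis
(absolute mL/min or per-kg mL/min/kg) of their inputs. Blood/plasma
distinctions are carried explicitly through the blood-to-plasma ratio ``R``
even though the shipped compounds have R = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "DerivationReport",
    "extraction_ratio",
    "correct_kpss_to_kp",
    "wellstirred_forward",
    "wellstirred_retrograde_hepatic",
    "wellstirred_retrograde_renal",
    "filtration_clearance",
    "secretion_clearance",
    "kpuu_psin_chain",
    "psout_from_pampa",
    "psout_from_uptake_protein",
    "apparent_invivo_permeability",
    "formation_clearance",
    "ivive_formation_clint",
    "scaling_factor",
]


@dataclass
class DerivationReport:
    """Flat audit record of named intermediate values with units."""

    values: dict[str, float] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, value: float, unit: str = "") -> None:
        if name.startswith(("ER_",)) or name == "ER":
            if not (0 <= value < 1):
                raise ValueError(f"{name}: extraction ratio must be in [0,1)")
        elif "CL" in name and value < 0:
            raise ValueError(f"{name}: clearance must be >= 0")
        self.values[name] = value
        self.units[name] = unit

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: {"value": v, "unit": self.units[k]}
                       for k, v in self.values.items()}, fh, indent=1)


def extraction_ratio(CL_org: float, Q_T: float, R: float = 1.0) -> float:
    """Organ extraction ratio: organ blood clearance over organ blood flow."""
    if CL_org < 0:
        raise ValueError("organ clearance must be >= 0")
    if CL_org >= Q_T * R:
        raise ValueError("organ clearance must be below organ blood flow "
                         "(perfusion-limited extraction cannot reach 1)")
    return CL_org / (Q_T * R)


def correct_kpss_to_kp(Kp_ss: float, ER: float) -> float:
    """Correct a steady-state tissue-to-plasma ratio of an eliminating organ
    to the equilibrium partition coefficient: Kp = Kp,ss / (1 - ER)."""
    if Kp_ss <= 0:
        raise ValueError("Kp,ss must be positive")
    if not (0 <= ER < 1):
        raise ValueError("extraction ratio must be in [0, 1)")
    return Kp_ss / (1.0 - ER)


def wellstirred_forward(CLu_int: float, Q: float, fup: float,
                        R: float = 1.0) -> float:
    """Forward well-stirred organ model: CL = Q·R·fup·CLu,int/(Q·R + fup·CLu,int)."""
    if CLu_int < 0:
        raise ValueError("intrinsic clearance must be >= 0")
    return Q * R * fup * CLu_int / (Q * R + fup * CLu_int)


def _wellstirred_retrograde(CL: float, Q: float, fup: float, R: float) -> float:
    if CL < 0:
        raise ValueError("clearance must be >= 0")
    if CL >= Q * R:
        raise ValueError("organ clearance must be below organ blood flow Q·R")
    if not (0 < fup <= 1):
        raise ValueError("fup must be in (0, 1]")
    return Q * R * CL / (fup * (Q * R - CL))


def wellstirred_retrograde_hepatic(CL_H: float, Q_H: float, fup: float,
                                   R: float = 1.0) -> float:
    """Retrograde well-stirred liver: hepatic blood clearance to unbound
    intrinsic clearance, CLu,int = Q_H·R·CL_H / (fup·(Q_H·R − CL_H))."""
    return _wellstirred_retrograde(CL_H, Q_H, fup, R)


def wellstirred_retrograde_renal(CLsec: float, Q_K: float, fup: float,
                                 R: float = 1.0) -> float:
    """Retrograde well-stirred kidney: secretion clearance to unbound renal
    secretory intrinsic clearance (same functional form, renal blood flow)."""
    return _wellstirred_retrograde(CLsec, Q_K, fup, R)


def filtration_clearance(fup: float, GFR: float, R: float = 1.0) -> float:
    """Unbound glomerular filtration clearance fup·GFR/R, on the basis
    (absolute or per-kg) of the supplied GFR."""
    if fup < 0 or GFR < 0 or R <= 0:
        raise ValueError("inputs must be non-negative (R positive)")
    return fup * GFR / R


def secretion_clearance(CL: float, fe: float, fup: float, GFR: float,
                        R: float = 1.0) -> float:
    """Net tubular secretion clearance CLsec = CL·fe − fup·GFR/R.

    Assumes no net reabsorption; a negative result is rejected because it
    indicates a net-reabsorption regime this decomposition cannot describe.
    """
    clsec = CL * fe - filtration_clearance(fup, GFR, R)
    if clsec < 0:
        raise ValueError(
            "CL·fe < fup·GFR/R: net-reabsorption regime; secretion clearance "
            "cannot be obtained by filtration subtraction")
    return clsec


def kpuu_psin_chain(Kp: float, fup: float, fu_tissue: float,
                    PS_out: float) -> tuple[float, float, float]:
    """Passive-partition chain: Kp,pass = fup/fu,tissue; Kp,uu = Kp/Kp,pass;
    PSin = Kp,uu·PSout. Returns (Kp_pass, Kp_uu, PS_in)."""
    if min(Kp, fup, fu_tissue, PS_out) <= 0:
        raise ValueError("all inputs must be positive")
    kp_pass = fup / fu_tissue
    kp_uu = Kp / kp_pass
    return kp_pass, kp_uu, kp_uu * PS_out


def psout_from_pampa(Papp: float, Seff_per_g: float, tissue_mass: float) -> float:
    """Passive basolateral efflux clearance from PAMPA permeability:
    PSout (mL/min) = Papp (cm/s) × Seff (cm²/g) × mass (g) × 60 s/min."""
    if Papp < 0 or Seff_per_g < 0 or tissue_mass < 0:
        raise ValueError("inputs must be non-negative")
    return Papp * Seff_per_g * tissue_mass * 60.0


def psout_from_uptake_protein(uptake: float, interval: float,
                              protein_per_g: float,
                              compartment_mass: float) -> float:
    """Passive efflux clearance from a cell-uptake rate:
    PSout (mL/min) = (uptake uL/mg / interval min) × protein mg/g × mass g / 1000."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    if min(uptake, protein_per_g, compartment_mass) < 0:
        raise ValueError("inputs must be non-negative")
    return uptake / interval * protein_per_g * compartment_mass / 1000.0


def apparent_invivo_permeability(fup: float, Papp: float,
                                 R: float = 1.0) -> float:
    """In-vivo apparent passive permeability fup·Papp/R (cm/s)."""
    if fup < 0 or Papp < 0 or R <= 0:
        raise ValueError("inputs must be non-negative (R positive)")
    return fup * Papp / R


def formation_clearance(AUC_ratio: float, CL_m_disposition: float) -> float:
    """Metabolite formation clearance CLm = (AUC_m/AUC_p) × CL(m), where
    CL(m) is the metabolite's own disposition clearance."""
    if AUC_ratio < 0 or CL_m_disposition < 0:
        raise ValueError("inputs must be non-negative")
    return AUC_ratio * CL_m_disposition


def ivive_formation_clint(rate: float, substrate_conc: float,
                          protein_per_g_liver: float,
                          liver_mass: float) -> float:
    """Scale an in-vitro formation rate (pmol/min/mg protein at a sub-Km
    substrate concentration, uM) to a whole-liver intrinsic clearance:
    CLint (mL/min) = rate/[S] × protein mg/g × liver g / 1000."""
    if substrate_conc <= 0:
        raise ValueError("substrate concentration must be positive")
    if min(rate, protein_per_g_liver, liver_mass) < 0:
        raise ValueError("inputs must be non-negative")
    return rate / substrate_conc * protein_per_g_liver * liver_mass / 1000.0


def scaling_factor(in_vivo: float, in_vitro: float) -> float:
    """Empirical IVIVE scaling factor: in-vivo over in-vitro intrinsic CL."""
    if in_vitro <= 0 or in_vivo < 0:
        raise ValueError("clearances must be positive")
    return in_vivo / in_vitro
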