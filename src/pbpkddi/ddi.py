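"""Drug-drug-interaction evaluation: exposure/excretion endpoints, arm
ratios, prediction-accuracy metrics, and inhibition-constant sensitivity.

Endpoints per compound and arm: AUC(0-inf) of plasma concentration, renal
clearance CL_R = cumulative urinary excretion over AUC, and urinary recovery
as % of dose. Interaction magnitude is the with-perpetrator over control
ratio of each endpoint. Prediction accuracy against observations uses the
absolute average fold error AAFE = 10^(mean |log10(pred/obs)|).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelConfig, SimulationResult, simulate
from .nca import auc_trapezoid
from .params import DoseRegimen, REFERENCE_BW_KG

__all__ = [
    "aafe", "ArmEndpoints", "DDIReport", "endpoints_from_simulation",
    "ddi_ratios", "ki_sensitivity", "DEFAULT_KI_MULTIPLIERS",
]

#: Half-decade multiplier grid spanning 10^-2 .. 10^2 for Ki sensitivity.
DEFAULT_KI_MULTIPLIERS = tuple(10.0 ** e for e in np.arange(-2, 2.01, 0.5))


def aafe(pred, obs) -> float:
    """Absolute average fold error 10^(mean |log10(pred/obs)|); 1 is a
    perfect prediction, 2 means twofold average discrepancy."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("pred and obs must be positive")
    return float(10.0 ** np.mean(np.abs(np.log10(p / o))))


@dataclass
class ArmEndpoints:
    """Model endpoints for one compound in one arm."""

    AUC_inf: float        # ug*min/mL
    CL: float             # mL/min/kg (dose-based; NaN for an undosed compound)
    CL_R: float           # mL/min/kg
    urine_pct_dose: float # % of the (parent) dose excreted by t_end
    Cmax: float           # ug/mL


def endpoints_from_simulation(res: SimulationResult, compound: str,
                              dosed: str | None = None,
                              BW: float = REFERENCE_BW_KG) -> ArmEndpoints:
    """Endpoints from a simulated arm. The simulation grid should extend to
    effective completion of excretion; AUC uses the log-trapezoid on the
    simulated grid plus terminal extrapolation from the last two points."""
    conc = res.concentration(compound, "plasma")
    t = res.t
    auc, _ = auc_trapezoid(t, conc)
    # terminal extrapolation from the final simulated decade
    c1, c2 = conc[-2], conc[-1]
    if c2 > 0 and c1 > c2:
        lz = np.log(c1 / c2) / (t[-1] - t[-2])
        auc += c2 / lz
    dosed = dosed or compound
    dose_ug_per_kg = res.dose_nmol[dosed] * res.mw[dosed] / 1000.0 / BW
    xe_ug_per_kg = res.urine_amount_mg(compound)[-1] * 1000.0 / BW
    own_dose = res.dose_nmol.get(compound, 0.0)
    own_ug_per_kg = own_dose * res.mw[compound] / 1000.0 / BW
    return ArmEndpoints(
        AUC_inf=float(auc),
        CL=float(own_ug_per_kg / auc) if own_dose else float("nan"),
        CL_R=float(xe_ug_per_kg / auc),
        urine_pct_dose=float(res.urine_pct_dose(compound, of=dosed)[-1]),
        Cmax=float(conc.max()))


@dataclass
class DDIReport:
    control: dict[str, ArmEndpoints]
    ddi: dict[str, ArmEndpoints]
    auc_ratio: dict[str, float] = field(default_factory=dict)
    clr_ratio: dict[str, float] = field(default_factory=dict)
    recovery_ratio: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.control:
            ctl, trt = self.control[c], self.ddi[c]
            self.auc_ratio[c] = trt.AUC_inf / ctl.AUC_inf
            self.clr_ratio[c] = trt.CL_R / ctl.CL_R
            self.recovery_ratio[c] = (trt.urine_pct_dose
                                      / ctl.urine_pct_dose)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.control:
            for arm, ep in (("control", self.control[c]), ("ddi", self.ddi[c])):
                rows.append((c, arm, ep.AUC_inf, ep.CL, ep.CL_R,
                             ep.urine_pct_dose, ep.Cmax))
        return pd.DataFrame(rows, columns=[
            "compound", "arm", "AUC_inf", "CL", "CL_R",
            "urine_pct_dose", "Cmax"])


def ddi_ratios(control: SimulationResult, ddi: SimulationResult,
               compounds: list[str], dosed: str | None = None,
               BW: float = REFERENCE_BW_KG) -> DDIReport:
    """Endpoint ratios (with-perpetrator over control) for each victim.

    ``dosed`` names the administered compound when a listed compound is a
    metabolite of it (recoveries are then expressed as % of that dose)."""
    ctl = {c: endpoints_from_simulation(control, c, dosed, BW)
           for c in compounds}
    trt = {c: endpoints_from_simulation(ddi, c, dosed, BW)
           for c in compounds}
    return DDIReport(control=ctl, ddi=trt)


def ki_sensitivity(cfg: ModelConfig, control_regimen: DoseRegimen,
                   ddi_regimen: DoseRegimen, t_end: float,
                   compounds: list[str], dosed: str | None = None,
                   targets: tuple[str, ...] = ("Ki_OCT2", "Ki_MATE1"),
                   multipliers=DEFAULT_KI_MULTIPLIERS,
                   t_eval: np.ndarray | None = None) -> pd.DataFrame:
    """Sweep each inhibition constant over multiplicative perturbations and
    record the resulting endpoint ratios.

    One constant moves at a time (the other stays at its base value). The
    control arm is simulated once. Returns a tidy frame with columns
    target, multiplier, Ki, compound, endpoint, ratio.
    """
    base = cfg.drugs[cfg.perpetrator]
    ctl = simulate(cfg, control_regimen, t_end, t_eval=t_eval)
    rows = []
    for target in targets:
        k0 = getattr(base, target)
        if k0 is None:
            raise ValueError(f"perpetrator has no {target}")
        for m in multipliers:
            drugs = dict(cfg.drugs)
            drugs[cfg.perpetrator] = base.with_(**{target: k0 * m})
            res = simulate(replace(cfg, drugs=drugs), ddi_regimen, t_end,
                           t_eval=t_eval)
            rep = ddi_ratios(ctl, res, compounds, dosed)
            for c in compounds:
                rows.append((target, m, k0 * m, c, "auc_ratio",
                             rep.auc_ratio[c]))
                rows.append((target, m, k0 * m, c, "clr_ratio",
                             rep.clr_ratio[c]))
                rows.append((target, m, k0 * m, c, "recovery_ratio",
                             rep.recovery_ratio[c]))
    return pd.DataFrame(rows, columns=["target", "multiplier", "Ki",
                                       "compound", "endpoint", "ratio"])
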