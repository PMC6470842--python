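"""Noncompartmental analysis of plasma concentration-time and interval-urine
data.

AUC uses the linear-up/log-down trapezoid (log rule only when both
concentrations are positive and declining). The terminal slope is chosen by
log-linear regression over trailing windows of at least three points,
excluding Cmax, maximising adjusted R^2 (ties favour more points). Renal
clearance is cumulative urinary recovery over AUC to infinity; analyses are
per animal, with summary statistics taken over per-animal parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import REFERENCE_BW_KG

__all__ = [
    "ConcentrationTimeProfile", "UrineCollection", "NCAResult",
    "auc_trapezoid", "lambda_z", "renal_clearance", "summarize",
]


@dataclass
class ConcentrationTimeProfile:
    times: np.ndarray            # min, strictly increasing
    concentrations: np.ndarray   # ug/mL, >= 0
    dose_mg: float               # administered dose (of the dosed compound)
    subject: str = ""
    route: str = "iv_bolus"
    BW: float = REFERENCE_BW_KG

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def dose_ug_per_kg(self) -> float:
        return self.dose_mg * 1000.0 / self.BW


@dataclass
class UrineCollection:
    """One urine collection interval."""
    t_start_h: float
    t_end_h: float
    volume_ml: float
    concentration_ug_ml: float

    @property
    def amount_ug(self) -> float:
        return self.volume_ml * self.concentration_ug_ml


def _check_contiguous(urine: list[UrineCollection]) -> None:
    urine = sorted(urine, key=lambda u: u.t_start_h)
    for a, b in zip(urine, urine[1:]):
        if not math.isclose(a.t_end_h, b.t_start_h, abs_tol=1e-9):
            raise ValueError("urine intervals must be contiguous and "
                             "non-overlapping")
    if any(u.volume_ml < 0 or u.concentration_ug_ml < 0 for u in urine):
        raise ValueError("urine volumes and concentrations must be >= 0")


@dataclass
class NCAResult:
    AUC_last: float
    AUC_inf: float
    AUMC_inf: float
    lambda_z: float
    lambda_z_n_points: int
    lambda_z_adj_r2: float
    t_half: float          # min
    MRT: float             # min
    CL: float              # mL/min/kg
    Vss: float             # mL/kg
    Cmax: float            # ug/mL
    Tmax: float            # min
    CL_R: float | None = None    # mL/min/kg
    CL_NR: float | None = None   # mL/min/kg
    Xe_0_24_pct: float | None = None
    extras: dict = field(default_factory=dict)


def auc_trapezoid(times, conc) -> tuple[float, float]:
    """(AUC_last, AUMC_last) by the linear-up/log-down trapezoid."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise ValueError("at least two points required")
    auc = aumc = 0.0
    for i in range(t.size - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        dt = t2 - t1
        if c1 > 0 and c2 > 0 and c2 < c1:
            k = math.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / k ** 2
        else:
            auc += 0.5 * (c1 + c2) * dt
            aumc += 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def lambda_z(profile: ConcentrationTimeProfile, min_points: int = 3
             ) -> tuple[float, int, float]:
    """Terminal elimination rate constant by best-adjusted-R^2 log-linear
    regression over trailing windows (Cmax excluded).

    Returns (lambda_z, n_points, adjusted_R2). Raises if no window gives a
    positive elimination slope.
    """
    t, c = profile.times, profile.concentrations
    pos = c > 0
    i_cmax = int(np.argmax(c))
    best = None
    n = t.size
    for start in range(n - min_points, -1, -1):
        idx = [i for i in range(start, n) if pos[i] and i > i_cmax]
        if len(idx) < min_points:
            continue
        x, y = t[idx], np.log(c[idx])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        m = len(idx)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2) if m > 2 else r2
        # ties (within 1e-10) favour more points; windows grow backwards
        if best is None or adj > best[2] + 1e-10 or (
                abs(adj - best[2]) <= 1e-10 and m > best[1]):
            best = (-slope, m, adj)
    if best is None:
        raise ValueError("no terminal window with a positive elimination "
                         "slope (non-declining profile?)")
    return best


def renal_clearance(urine: list[UrineCollection], AUC_inf: float,
                    dose_ug_per_kg: float, BW: float = REFERENCE_BW_KG
                    ) -> tuple[float, float]:
    """Renal clearance CL_R = Xe(0-24h)/AUC_inf (mL/min/kg) and the urinary
    recovery Xe as % of dose. Collections must cover 0-24 h."""
    if AUC_inf <= 0:
        raise ValueError("AUC_inf must be positive")
    _check_contiguous(urine)
    span = (min(u.t_start_h for u in urine), max(u.t_end_h for u in urine))
    if span[0] > 1e-9 or span[1] < 24 - 1e-9:
        raise ValueError(f"urine collections must cover 0-24 h, got {span}")
    xe_ug_per_kg = sum(u.amount_ug for u in urine) / BW
    cl_r = xe_ug_per_kg / AUC_inf
    xe_pct = (100.0 * xe_ug_per_kg / dose_ug_per_kg
              if dose_ug_per_kg > 0 else 0.0)
    return cl_r, xe_pct


def summarize(profile: ConcentrationTimeProfile,
              urine: list[UrineCollection] | None = None,
              min_points: int = 3) -> NCAResult:
    """Full per-animal NCA: AUC/AUMC with log-trapezoid and terminal-slope
    extrapolation, CL = dose/AUC_inf, MRT = AUMC_inf/AUC_inf, Vss = CL*MRT
    (iv bolus), renal split when urine is supplied."""
    t, c = profile.times, profile.concentrations
    auc_last, aumc_last = auc_trapezoid(t, c)
    lz, npts, adj = lambda_z(profile, min_points)
    c_last, t_last = c[-1], t[-1]
    auc_inf = auc_last + c_last / lz
    aumc_inf = aumc_last + c_last * t_last / lz + c_last / lz ** 2
    cl = profile.dose_ug_per_kg / auc_inf
    mrt = aumc_inf / auc_inf
    i_max = int(np.argmax(c))
    res = NCAResult(
        AUC_last=auc_last, AUC_inf=auc_inf, AUMC_inf=aumc_inf,
        lambda_z=lz, lambda_z_n_points=npts, lambda_z_adj_r2=adj,
        t_half=math.log(2) / lz, MRT=mrt, CL=cl, Vss=cl * mrt,
        Cmax=float(c[i_max]), Tmax=float(t[i_max]))
    if urine is not None:
        cl_r, xe = renal_clearance(urine, auc_inf, profile.dose_ug_per_kg,
                                   profile.BW)
        res.CL_R = cl_r
        res.CL_NR = cl - cl_r
        res.Xe_0_24_pct = xe
    return res
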