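"""Parameter estimation against (synthetic or external) observations.

Two estimators:

* ``fit_clu_int_r`` — the renal secretory intrinsic clearance of one victim
  compound, by least squares on log-transformed plasma concentrations and
  interval urine amounts, with the rest of the whole-body model fixed.
  Parent and metabolite are fitted sequentially (parent first; its estimate
  is plugged in before the metabolite fit, matching the model's one-way
  parent-to-metabolite coupling).
* ``fit_minimal_pbpk`` — the distribution parameters of the minimal
  perpetrator model (central volume and, per variant, one or two
  peripheral volume/clearance pairs), with non-renal clearance and the
  mechanistic kidney fixed. Variants are ranked by AIC = n ln(SSR/n) + 2p.

All parameters are estimated on the log scale (positivity, multiplicative
error); reported CV% are asymptotic, from the Jacobian at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import ModelConfig, build_perpetrator_system, simulate
from .params import DoseRegimen, MinimalPBPKParams
from scipy.linalg import expm

__all__ = [
    "EstimateResult", "MinimalFit", "fit_clu_int_r",
    "fit_clu_int_r_sequential", "fit_minimal_pbpk", "aic",
]


def aic(ssr: float, n: int, n_params: int) -> float:
    """Least-squares Akaike information criterion n ln(SSR/n) + 2p."""
    if ssr <= 0 or n <= 0:
        raise ValueError("SSR and n must be positive")
    return n * math.log(ssr / n) + 2 * n_params


@dataclass
class EstimateResult:
    name: str
    value: float
    cv_pct: float | None
    ssr: float
    n: int
    nfev: int
    extras: dict = field(default_factory=dict)


def _cv_from_jacobian(res, log_scale: bool = True) -> list[float | None]:
    """Asymptotic CV% per parameter from a scipy least_squares result whose
    parameters are natural logs of the physical values."""
    m, p = res.fun.size, res.x.size
    if m <= p:
        return [None] * p
    s2 = float(res.fun @ res.fun) / (m - p)
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return [None] * p
    out = []
    for k in range(p):
        var = cov[k, k]
        if not np.isfinite(var) or var < 0:
            out.append(None)
        elif log_scale:
            # sd of ln(theta) approximates the CV of theta
            out.append(100.0 * math.sqrt(var))
        else:
            out.append(100.0 * math.sqrt(var) / abs(res.x[k]))
    return out


def _observation_vectors(plasma: pd.DataFrame, urine: pd.DataFrame | None):
    """Pool log-observations: (plasma times, log conc) and per-interval
    (bounds, log amount). Non-positive observations are dropped."""
    pl = plasma[plasma["conc_ug_ml"] > 0]
    times = pl["time_min"].to_numpy(dtype=float)
    logc = np.log(pl["conc_ug_ml"].to_numpy(dtype=float))
    intervals, loga = [], []
    if urine is not None and len(urine):
        u = urine.copy()
        if "amount_mg" not in u.columns:
            u["amount_mg"] = u["volume_ml"] * u["conc_ug_ml"] / 1000.0
        u = u[u["amount_mg"] > 0]
        intervals = list(zip(u["t_start_h"].astype(float),
                             u["t_end_h"].astype(float)))
        loga = list(np.log(u["amount_mg"].to_numpy(dtype=float)))
    return times, logc, intervals, np.asarray(loga)


def fit_clu_int_r(cfg: ModelConfig, regimen: DoseRegimen, compound: str,
                  plasma: pd.DataFrame, urine: pd.DataFrame | None = None,
                  bounds: tuple[float, float] = (1e-4, 1e4),
                  x0: float | None = None) -> EstimateResult:
    """Estimate one compound's renal secretory intrinsic clearance.

    ``plasma`` needs columns time_min/conc_ug_ml (any subject column is
    pooled); ``urine`` needs t_start_h/t_end_h and either amount_mg or
    volume_ml+conc_ug_ml. Returns the estimate with asymptotic CV%.
    """
    drug = cfg.drugs[compound]
    times, logc, intervals, loga = _observation_vectors(plasma, urine)
    if times.size + loga.size < 2:
        raise ValueError("need at least two positive observations")
    bounds_min = sorted({b * 60.0 for iv in intervals for b in iv})
    grid = np.array(sorted(set(times) | set(bounds_min) | {0.0}))
    t_end = float(grid[-1])
    ip = np.searchsorted(grid, times)

    def predict(theta: float):
        drugs = dict(cfg.drugs)
        drugs[compound] = drug.with_(CLu_int_r=theta)
        res = simulate(replace(cfg, drugs=drugs), regimen, t_end, t_eval=grid)
        conc = res.concentration(compound, "plasma")
        urine_mg = res.urine_amount_mg(compound)
        pc = np.maximum(conc[ip], 1e-300)
        pu = []
        for a, b in intervals:
            ia, ib = np.searchsorted(grid, [a * 60.0, b * 60.0])
            pu.append(max(urine_mg[ib] - urine_mg[ia], 1e-300))
        return np.log(pc), np.log(np.asarray(pu))

    def residuals(x):
        lp, lu = predict(math.exp(x[0]))
        r = []
        if times.size:
            r.append(lp - logc)
        if loga.size:
            r.append(lu - loga)
        return np.concatenate(r)

    start = math.log(x0 if x0 is not None else max(drug.CLu_int_r, 1e-2))
    res = least_squares(residuals, x0=[start],
                        bounds=([math.log(bounds[0])], [math.log(bounds[1])]),
                        xtol=1e-10, ftol=1e-12)
    cv = _cv_from_jacobian(res)[0]
    return EstimateResult(
        name=f"CLu_int_r[{compound}]", value=float(math.exp(res.x[0])),
        cv_pct=cv, ssr=float(res.fun @ res.fun), n=int(res.fun.size),
        nfev=int(res.nfev))


def fit_clu_int_r_sequential(cfg: ModelConfig, regimen: DoseRegimen,
                             plasma: pd.DataFrame,
                             urine: pd.DataFrame | None = None,
                             ) -> dict[str, EstimateResult]:
    """Fit the parent's CLu,int,r, plug the estimate into the model, then fit
    the metabolite's. Tables are filtered by their ``compound`` column."""
    out: dict[str, EstimateResult] = {}
    cfg_cur = cfg
    targets = [cfg.parent] + ([cfg.metabolite] if cfg.metabolite else [])
    for c in targets:
        pl = plasma[plasma["compound"] == c]
        ur = urine[urine["compound"] == c] if urine is not None else None
        est = fit_clu_int_r(cfg_cur, regimen, c, pl, ur)
        out[c] = est
        drugs = dict(cfg_cur.drugs)
        drugs[c] = drugs[c].with_(CLu_int_r=est.value)
        cfg_cur = replace(cfg_cur, drugs=drugs)
    return out


# ---------------------------------------------------------------------------
# minimal perpetrator distribution model


@dataclass
class MinimalFit:
    n_compartments: int
    params: MinimalPBPKParams
    cv_pct: dict[str, float | None]
    ssr: float
    n: int
    aic: float
    nfev: int


_VARIANT_PARAMS = {1: ("VC",), 2: ("VC", "V1", "CLD1"),
                   3: ("VC", "V1", "CLD1", "V2", "CLD2")}


def _perp_concentrations(cfg: ModelConfig, minimal: MinimalPBPKParams,
                         n_peripheral: int, dose_nmol: float,
                         times: np.ndarray) -> np.ndarray:
    """Central concentration (uM) after an iv bolus, by exact matrix
    exponential on the (time-invariant) minimal system."""
    sys = build_perpetrator_system(replace(cfg, minimal=minimal),
                                  n_peripheral=n_peripheral)
    x = np.zeros(sys.n)
    cen = sys.index[cfg.perpetrator + ".central"]
    x[cen] = dose_nmol
    out = np.empty(times.size)
    t_prev = 0.0
    for k, t in enumerate(times):
        h = t - t_prev
        if h > 0:
            x = expm(sys.A0 * h) @ x
            t_prev = t
        out[k] = x[cen] / minimal.VC
    return out


def fit_minimal_pbpk(cfg: ModelConfig, times, conc_ug_ml, dose_nmol: float,
                     n_compartments: int = 3) -> MinimalFit:
    """Fit the perpetrator's distribution parameters to a plasma profile.

    ``n_compartments`` counts total compartments (1 = central only,
    2 = one peripheral, 3 = two peripherals). Non-renal clearance and the
    kidney submodel stay at their configured values; only volumes and
    distributional clearances are free. Residuals are log-concentration.
    """
    if cfg.minimal is None or cfg.perpetrator is None:
        raise ValueError("config has no perpetrator/minimal model")
    if n_compartments not in _VARIANT_PARAMS:
        raise ValueError("n_compartments must be 1, 2 or 3")
    free = _VARIANT_PARAMS[n_compartments]
    n_peripheral = n_compartments - 1
    mw = cfg.drugs[cfg.perpetrator].MW
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc_ug_ml, dtype=float)
    keep = c > 0
    t, c = t[keep], c[keep]
    if t.size <= len(free):
        raise ValueError("more positive observations than free parameters "
                         "are required")
    logc_um = np.log(c * 1000.0 / mw)  # observed uM
    order = np.argsort(t)
    t, logc_um = t[order], logc_um[order]

    base = cfg.minimal

    def make_minimal(x) -> MinimalPBPKParams:
        vals = dict(VC=base.VC, V1=base.V1, V2=base.V2,
                    CLD1=base.CLD1, CLD2=base.CLD2, CL_H=base.CL_H)
        for name, xv in zip(free, x):
            vals[name] = math.exp(xv)
        return MinimalPBPKParams(**vals)

    def residuals(x):
        m = make_minimal(x)
        pred = _perp_concentrations(cfg, m, n_peripheral, dose_nmol, t)
        return np.log(np.maximum(pred, 1e-300)) - logc_um

    # data-driven central-volume start; literature-magnitude defaults for the
    # peripheral terms
    vc0 = dose_nmol / math.exp(logc_um[0])
    starts = {"VC": vc0, "V1": vc0, "CLD1": 10.0, "V2": 2 * vc0, "CLD2": 1.0}
    x0 = [math.log(starts[p]) for p in free]
    res = least_squares(residuals, x0=x0, xtol=1e-12, ftol=1e-12)
    fitted = make_minimal(res.x)
    cvs = _cv_from_jacobian(res)
    ssr = float(res.fun @ res.fun)
    return MinimalFit(
        n_compartments=n_compartments, params=fitted,
        cv_pct=dict(zip(free, cvs)), ssr=ssr, n=int(t.size),
        aic=aic(ssr, int(t.size), len(free)), nfev=int(res.nfev))
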