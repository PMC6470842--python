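"""In-vitro metabolite-formation inhibition kinetics.

Formation rates (pmol/min/mg protein) from incubation measurements, and an
IC50 fit of the inhibitable fraction of activity with a two-parameter model
v = vmax / (1 + [I]/IC50), estimated by nonlinear least squares (lmfit) with
asymptotic confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

__all__ = [
    "InhibitionDataset", "InhibitionFit", "formation_rate",
    "percent_activity", "fit_ic50", "DEFAULT_INHIBITOR_CONCS",
]

#: Inhibitor concentration grid (uM) of the shipped incubation design.
DEFAULT_INHIBITOR_CONCS = (0.0, 0.5, 1.0, 5.0, 10.0, 50.0,
                           100.0, 500.0, 1000.0, 5000.0)


@dataclass
class InhibitionDataset:
    """Formation rates measured across inhibitor concentrations.

    ``inhibitor_conc`` in uM, ``rates`` in pmol/min/mg protein. Replicates
    appear as repeated concentrations.
    """

    inhibitor_conc: np.ndarray
    rates: np.ndarray
    substrate_conc: float | None = None   # uM, for downstream IVIVE
    label: str = ""

    def __post_init__(self) -> None:
        self.inhibitor_conc = np.asarray(self.inhibitor_conc, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.inhibitor_conc.shape != self.rates.shape or \
                self.inhibitor_conc.ndim != 1:
            raise ValueError("inhibitor_conc and rates must be 1-D and "
                             "equal length")
        if np.any(self.inhibitor_conc < 0):
            raise ValueError("inhibitor concentrations must be >= 0")
        if np.any(self.rates < 0):
            raise ValueError("formation rates must be >= 0")
        if np.unique(self.inhibitor_conc).size < 4:
            raise ValueError("at least four distinct inhibitor "
                             "concentrations are required for an IC50 fit")


def formation_rate(amount_pmol: float, incubation_min: float,
                   protein_mg: float) -> float:
    """Metabolite formation rate (pmol/min/mg protein) from the amount
    formed over a linear incubation."""
    if incubation_min <= 0 or protein_mg <= 0:
        raise ValueError("incubation time and protein amount must be positive")
    if amount_pmol < 0:
        raise ValueError("amount formed must be >= 0")
    return amount_pmol / incubation_min / protein_mg


def percent_activity(rates: np.ndarray, v0: float) -> np.ndarray:
    """Rates as percent of the uninhibited control activity ``v0``."""
    if v0 <= 0:
        raise ValueError("control activity must be positive")
    return 100.0 * np.asarray(rates, dtype=float) / v0


def _ic50_model(I, vmax, ic50):
    return vmax / (1.0 + I / ic50)


@dataclass
class InhibitionFit:
    vmax: float
    ic50: float
    vmax_stderr: float | None
    ic50_stderr: float | None
    ic50_ci95: tuple[float, float] | None
    ssr: float
    n: int
    result: object = field(repr=False, default=None)

    def predict(self, I) -> np.ndarray:
        return _ic50_model(np.asarray(I, dtype=float), self.vmax, self.ic50)


def fit_ic50(data: InhibitionDataset) -> InhibitionFit:
    """Fit v = vmax/(1 + [I]/IC50) by unweighted nonlinear least squares.

    IC50 is estimated on the log scale (positivity and a roughly symmetric
    error distribution); the reported 95% CI is the asymptotic Wald interval
    on that scale, transformed back.
    """
    I, v = data.inhibitor_conc, data.rates
    v0 = float(np.mean(v[I == I.min()])) if np.any(I == 0) else float(v.max())
    if v0 <= 0:
        raise ValueError("uninhibited activity must be positive")

    def model(I, vmax, log_ic50):
        return _ic50_model(I, vmax, 10.0 ** log_ic50)

    m = Model(model)
    # start IC50 at the concentration nearest half-maximal activity
    half = I[np.argmin(np.abs(v - v0 / 2))]
    half = half if half > 0 else np.median(I[I > 0])
    params = m.make_params(vmax=dict(value=v0, min=1e-12),
                           log_ic50=dict(value=float(np.log10(half)),
                                         min=-6, max=9))
    res = m.fit(v, params, I=I)
    vmax = float(res.params["vmax"].value)
    log_ic50 = float(res.params["log_ic50"].value)
    ic50 = 10.0 ** log_ic50
    se_v = res.params["vmax"].stderr
    se_l = res.params["log_ic50"].stderr
    ci = None
    ic50_stderr = None
    if se_l is not None and np.isfinite(se_l):
        ci = (10.0 ** (log_ic50 - 1.96 * se_l),
              10.0 ** (log_ic50 + 1.96 * se_l))
        ic50_stderr = ic50 * np.log(10.0) * se_l  # delta method
    return InhibitionFit(
        vmax=vmax, ic50=ic50,
        vmax_stderr=None if se_v is None else float(se_v),
        ic50_stderr=ic50_stderr, ic50_ci95=ci,
        ssr=float(np.sum(res.residual ** 2)), n=int(v.size), result=res)
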