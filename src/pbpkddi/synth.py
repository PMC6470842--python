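"""Synthetic study generation: simulate the model at a realistic sampling
design and add seeded measurement noise.

Noise is multiplicative log-normal, parameterised by the coefficient of
variation of the measurement: c_obs = c_true * exp(sigma * Z) with
sigma = sqrt(ln(1 + CV^2)), so the sampled CV matches the nominal one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelConfig, simulate
from .params import DoseRegimen
from .invitro import InhibitionDataset, DEFAULT_INHIBITOR_CONCS, _ic50_model

__all__ = [
    "NoiseModel", "PKStudy", "generate_pk_study", "generate_inhibition_study",
    "PLASMA_TIMES_MIN", "URINE_INTERVALS_H",
]

#: Shipped sampling design: ten post-dose plasma samples and five contiguous
#: urine collection intervals covering 0-24 h.
PLASMA_TIMES_MIN = (1.0, 5.0, 15.0, 30.0, 60.0, 120.0, 180.0, 240.0,
                    360.0, 480.0)
URINE_INTERVALS_H = ((0, 2), (2, 4), (4, 6), (6, 8), (8, 24))

#: Plausible rat urine volume per collection hour (mL/h); used to convert
#: simulated excreted amounts into volume/concentration pairs.
_URINE_ML_PER_H = 0.65


@dataclass
class NoiseModel:
    cv: float = 0.20
    seed: int = 0
    lloq: float = 0.0   # measurements below this are reported as 0

    def __post_init__(self) -> None:
        if not (0 <= self.cv < 1.5):
            raise ValueError("cv must be in [0, 1.5)")
        if self.lloq < 0:
            raise ValueError("lloq must be >= 0")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv ** 2)))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, values: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.cv == 0:
            out = values.copy()
        else:
            out = values * np.exp(self.sigma * rng.standard_normal(values.shape))
        out[out < self.lloq] = 0.0
        return out


@dataclass
class PKStudy:
    """Tidy synthetic study tables plus the noiseless truth."""

    plasma: pd.DataFrame   # subject, compound, time_min, conc_ug_ml
    urine: pd.DataFrame    # subject, compound, t_start_h, t_end_h,
    #                        volume_ml, conc_ug_ml
    truth_plasma: pd.DataFrame
    truth_urine: pd.DataFrame
    dose_mg: dict          # base-equivalent dose per dosed compound


def _truth_tables(cfg: ModelConfig, regimen: DoseRegimen,
                  compounds: list[str], plasma_times, urine_intervals):
    bounds_min = sorted({b * 60.0 for iv in urine_intervals for b in iv})
    grid = np.array(sorted(set(plasma_times) | set(bounds_min) | {0.0}))
    res = simulate(cfg, regimen, t_end=float(grid[-1]), t_eval=grid)

    prows, urows = [], []
    for c in compounds:
        conc = res.concentration(c, "plasma")
        for t in plasma_times:
            prows.append((c, t, float(conc[np.searchsorted(grid, t)])))
        urine_mg = res.urine_amount_mg(c)
        for a, b in urine_intervals:
            ia, ib = np.searchsorted(grid, [a * 60.0, b * 60.0])
            amt = float(urine_mg[ib] - urine_mg[ia])
            urows.append((c, float(a), float(b), amt))
    tp = pd.DataFrame(prows, columns=["compound", "time_min", "conc_ug_ml"])
    tu = pd.DataFrame(urows, columns=["compound", "t_start_h", "t_end_h",
                                      "amount_mg"])
    return tp, tu, res


def generate_pk_study(cfg: ModelConfig, regimen: DoseRegimen,
                      compounds: list[str] | None = None,
                      noise: NoiseModel | None = None,
                      n_subjects: int = 4,
                      plasma_times=PLASMA_TIMES_MIN,
                      urine_intervals=URINE_INTERVALS_H) -> PKStudy:
    """Simulate the regimen once and emit per-subject noisy observations.

    Plasma concentrations get multiplicative log-normal error; urine amounts
    get the same error applied to the interval amount, reported as a fixed
    physiological collection volume with the matching concentration.
    """
    if compounds is None:
        compounds = [cfg.parent] + ([cfg.metabolite] if cfg.metabolite else [])
    if noise is None:
        noise = NoiseModel()
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")

    tp, tu, res = _truth_tables(cfg, regimen, compounds,
                                plasma_times, urine_intervals)
    rng = noise.rng()
    prows, urows = [], []
    for s in range(1, n_subjects + 1):
        sid = f"rat{s:02d}"
        obs_c = noise.perturb(tp["conc_ug_ml"].to_numpy(), rng)
        for (row, c) in zip(tp.itertuples(index=False), obs_c):
            prows.append((sid, row.compound, row.time_min, float(c)))
        obs_a = noise.perturb(tu["amount_mg"].to_numpy(), rng)
        for (row, amt) in zip(tu.itertuples(index=False), obs_a):
            vol = _URINE_ML_PER_H * (row.t_end_h - row.t_start_h)
            urows.append((sid, row.compound, row.t_start_h, row.t_end_h,
                          vol, float(amt) * 1000.0 / vol))
    dose_mg = {c: res.dose_nmol[c] * res.mw[c] / 1e6
               for c in compounds if res.dose_nmol.get(c)}
    return PKStudy(
        plasma=pd.DataFrame(prows, columns=["subject", "compound",
                                            "time_min", "conc_ug_ml"]),
        urine=pd.DataFrame(urows, columns=["subject", "compound", "t_start_h",
                                           "t_end_h", "volume_ml",
                                           "conc_ug_ml"]),
        truth_plasma=tp, truth_urine=tu, dose_mg=dose_mg)


def generate_inhibition_study(vmax: float, ic50: float,
                              noise: NoiseModel | None = None,
                              concentrations=DEFAULT_INHIBITOR_CONCS,
                              replicates: int = 3,
                              substrate_conc: float | None = None,
                              label: str = "") -> InhibitionDataset:
    """Synthetic metabolite-formation inhibition experiment with replicate
    incubations and log-normal rate error."""
    if vmax <= 0 or ic50 <= 0:
        raise ValueError("vmax and ic50 must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise is None:
        noise = NoiseModel(cv=0.10)
    conc = np.repeat(np.asarray(concentrations, dtype=float), replicates)
    true = _ic50_model(conc, vmax, ic50)
    rates = noise.perturb(true, noise.rng())
    return InhibitionDataset(inhibitor_conc=conc, rates=rates,
                             substrate_conc=substrate_conc, label=label)
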