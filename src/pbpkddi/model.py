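"""Coupled PBPK systems: whole-body victim model (parent + metabolite), the
minimal perpetrator model, and the shared semi-mechanistic kidney submodel
with dynamic transporter inhibition.

Model structure
---------------
Victims (parent drug and its metabolite) get a whole-body model: ten
perfusion-limited tissues plus arterial/venous blood, lung in series with the
venous pool, the liver in the serial convention (gut and spleen drain through
it), hepatic elimination by the well-stirred convention (unbound emergent
venous concentration), and a semi-mechanistic kidney. The parent's hepatic
elimination converts a fraction ``F_NAPA`` of eliminated moles into the
metabolite's liver compartment.

The kidney comprises glomerular blood (GLM), renal blood (RBL), proximal
tubule cells (PTC), and six luminal segments whose filtrate flows are fixed
fractions of GFR. Filtration moves unbound drug from arterial blood into the
first luminal segment at fup·GFR/R; the basolateral membrane exchanges RBL
and PTC at PSin (uptake, inhibitable via OCT2) and PSout (passive efflux);
apical secretion into the proximal lumen proceeds at CLu,int,r (inhibitable
via MATE1) on the unbound cell concentration; luminal reabsorption returns
drug from the proximal segments to the cells at CL_rabs. Solute advances
between segments at the downstream segment's flow times the upstream
concentration, so water reabsorption concentrates solute in place; the
distal outflow runs into a cumulative urine compartment.

The perpetrator uses a fitted central + two-peripheral minimal model with
non-renal clearance from the central compartment and the same kidney
submodel attached by routing renal blood flow through it.

All balances are linear in drug amounts, so control arms are propagated
exactly with the matrix exponential; co-dosing arms make the victims'
transport coefficients time-varying through the perpetrator's unbound
concentrations and are integrated with an adaptive stiff solver (a
fixed-step classical Runge-Kutta integrator is available as an option).
Internal amounts are nmol; with volumes in mL, concentrations are nmol/mL,
numerically equal to uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .params import (
    PhysiologyParams, DrugParams, MinimalPBPKParams, DoseRegimen,
    convert_dose, SEGMENTS, PROXIMAL_SEGMENTS, TISSUES,
)
from .partition import predict_kp_rodgers_rowland  # noqa: F401  (re-export)

__all__ = [
    "ModelConfig", "SimulationResult", "apply_inhibition", "simulate",
    "build_victim_system", "build_perpetrator_system",
    "realized_reabsorbed_fraction", "total_moles",
    "predict_kp_rodgers_rowland",
]

# state layout of one whole-body victim block
VICTIM_COMPARTMENTS = (
    "venous", "lung", "arterial",
    "adipose", "bone", "brain", "gut", "heart", "muscle", "skin", "spleen",
    "liver",
    "GLM", "RBL", "PTC",
    "S1_1", "S1_2", "S1_3", "S2S3", "LOH", "DTCD",
    "urine", "sink", "cum_filtered", "cum_secreted",
)
N_VICTIM = len(VICTIM_COMPARTMENTS)

PERP_COMPARTMENTS = (
    "central", "peripheral_1", "peripheral_2",
    "GLM", "RBL", "PTC",
    "S1_1", "S1_2", "S1_3", "S2S3", "LOH", "DTCD",
    "urine", "sink",
)

_DIRECT_TISSUES = ("adipose", "bone", "brain", "heart", "muscle", "skin")


@dataclass
class ModelConfig:
    """Everything needed to assemble and integrate the coupled systems."""

    physiology: PhysiologyParams
    drugs: dict[str, DrugParams]
    minimal: MinimalPBPKParams | None = None
    parent: str = "PA"
    metabolite: str | None = "NAPA"
    perpetrator: str | None = "cimetidine"
    #: where secreted drug enters the lumen: spread over the four proximal
    #: segments in proportion to their volumes, or all into the first
    secretion_placement: str = "proximal"   # 'proximal' | 's1_1'
    reabsorption_placement: str = "proximal"
    #: perpetrator concentration driving OCT2 (basolateral) inhibition:
    #: unbound renal-blood or unbound central/plasma concentration
    oct2_driver: str = "renal_blood"        # 'renal_blood' | 'plasma'
    inhibit_metabolism: bool = False
    method: str = "auto"                    # 'auto' | 'lsoda' | 'rk4'
    rtol: float = 1e-8
    atol: float = 1e-10
    rk4_step: float = 0.01


# ---------------------------------------------------------------------------
# inhibition

def apply_inhibition(PS_in0: float, PS_out: float, CLu_int_r0: float,
                     Cu_oct2: float, Cu_mate1: float,
                     Ki_OCT2: float | None, Ki_MATE1: float | None,
                     ) -> tuple[float, float]:
    """Competitive inhibition of renal transport by the perpetrator.

    OCT2 inhibition scales only the active uptake component above the
    passive floor: PSin = PSout + (PSin0 − PSout)/(1 + Cu/Ki,OCT2).
    MATE1 inhibition scales the apical secretory intrinsic clearance:
    CLu,int,r = CLu,int,r0/(1 + Cu,cell/Ki,MATE1). Concentrations are
    unbound and in uM.
    """
    if Cu_oct2 < 0 or Cu_mate1 < 0:
        raise ValueError("inhibitor concentrations must be >= 0")
    if PS_in0 < PS_out:
        raise ValueError("PS_in must be >= PS_out (active uptake >= 0)")
    ps_in = PS_in0
    if Ki_OCT2 is not None:
        ps_in = PS_out + (PS_in0 - PS_out) / (1.0 + Cu_oct2 / Ki_OCT2)
    clu = CLu_int_r0
    if Ki_MATE1 is not None:
        clu = CLu_int_r0 / (1.0 + Cu_mate1 / Ki_MATE1)
    return ps_in, clu


# ---------------------------------------------------------------------------
# system assembly


class LinearSystem:
    """A (possibly time-varying) linear compartment system dx/dt = A(t)x + u.

    ``A0`` holds the uninhibited coefficients. ``tv_patterns`` lists
    (parameter_name, compound, base_value, entries) where ``entries`` are
    (row, col, coeff_per_unit_parameter); during co-dosing the effective
    parameter value replaces the base value and the listed entries are
    adjusted accordingly.
    """

    def __init__(self, names: list[str], volumes: dict[str, float | None]):
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.volumes = volumes
        self.n = len(names)
        self.A0 = np.zeros((self.n, self.n))
        self.tv_patterns: list[tuple[str, str, float, list[tuple[int, int, float]]]] = []

    def add_flow(self, row: str, col: str, clearance_over_volume: float) -> None:
        self.A0[self.index[row], self.index[col]] += clearance_over_volume

    def rhs_matrix(self, scale: dict[tuple[str, str], float] | None = None
                   ) -> np.ndarray:
        """A(t) for given effective parameter values keyed by
        (parameter_name, compound); missing keys keep base values."""
        A = self.A0.copy()
        if scale:
            for pname, compound, base, entries in self.tv_patterns:
                eff = scale.get((pname, compound))
                if eff is None or eff == base:
                    continue
                d = eff - base
                for i, j, c in entries:
                    A[i, j] += d * c
        return A


def _segment_arrays(phys: PhysiologyParams):
    seg_flow = phys.segment_flows()
    seg_vol = phys.segment_volumes()
    flows = [seg_flow[s] for s in SEGMENTS]
    vols = [seg_vol[s] for s in SEGMENTS]
    down = flows[1:] + [phys.Q_urine]   # downstream flow of each segment
    return flows, vols, down


def _placement_fractions(phys: PhysiologyParams, placement: str) -> list[float]:
    if placement == "s1_1":
        return [1.0, 0.0, 0.0, 0.0]
    if placement != "proximal":
        raise ValueError(f"unknown placement {placement!r}")
    v = [phys.segment_volumes()[s] for s in PROXIMAL_SEGMENTS]
    tot = sum(v)
    return [x / tot for x in v]


def _add_kidney(sys: LinearSystem, phys: PhysiologyParams, drug: DrugParams,
                prefix: str, art: str, venous_return: str | None,
                cfg_secretion: str, cfg_reabsorption: str,
                counters: bool) -> None:
    """Wire the semi-mechanistic kidney into ``sys``.

    ``art`` is the blood compartment feeding the kidney (arterial blood of
    the whole-body model, or the perpetrator's central compartment);
    ``venous_return`` receives the renal venous outflow (None routes it back
    to ``art``'s own pool, which is never the case here).
    """
    ix = sys.index
    V = sys.volumes
    QKI, fGFR = phys.QKI, drug.fup * phys.GFR / drug.R
    glm, rbl, ptc = prefix + "GLM", prefix + "RBL", prefix + "PTC"
    segs = [prefix + s for s in SEGMENTS]
    urine = prefix + "urine"

    c_art = 1.0 / V[art]
    # glomerular blood: inflow minus filtration, outflow to renal blood
    sys.add_flow(glm, art, (QKI - fGFR) * c_art)
    sys.add_flow(glm, glm, -QKI / V[glm])
    sys.add_flow(rbl, glm, QKI / V[glm])
    # renal venous return
    sys.add_flow(rbl, rbl, -QKI / V[rbl])
    sys.add_flow(venous_return, rbl, QKI / V[rbl])
    # filtration into the first luminal segment
    sys.add_flow(segs[0], art, fGFR * c_art)
    if counters:
        sys.add_flow(prefix + "cum_filtered", art, fGFR * c_art)

    # basolateral exchange (unbound): RBL <-> PTC
    fu_b = drug.fup / drug.R
    fu_k = drug.fu_kidney
    psin_entries = [
        (ix[rbl], ix[rbl], -fu_b / V[rbl]),
        (ix[ptc], ix[rbl], fu_b / V[rbl]),
    ]
    for i, j, c in psin_entries:
        sys.A0[i, j] += drug.PS_in * c
    sys.tv_patterns.append(("PS_in", drug.name, drug.PS_in, psin_entries))
    sys.add_flow(rbl, ptc, drug.PS_out * fu_k / V[ptc])
    sys.add_flow(ptc, ptc, -drug.PS_out * fu_k / V[ptc])

    # apical secretion into the proximal lumen
    sec_frac = _placement_fractions(phys, cfg_secretion)
    clu_entries = [(ix[ptc], ix[ptc], -fu_k / V[ptc])]
    for s, f in zip(PROXIMAL_SEGMENTS, sec_frac):
        if f:
            clu_entries.append((ix[prefix + s], ix[ptc], f * fu_k / V[ptc]))
    if counters:
        clu_entries.append((ix[prefix + "cum_secreted"], ix[ptc], fu_k / V[ptc]))
    for i, j, c in clu_entries:
        sys.A0[i, j] += drug.CLu_int_r * c
    sys.tv_patterns.append(("CLu_int_r", drug.name, drug.CLu_int_r, clu_entries))

    # luminal reabsorption back into the cells
    rabs_frac = _placement_fractions(phys, cfg_reabsorption)
    for s, f in zip(PROXIMAL_SEGMENTS, rabs_frac):
        cl = drug.CL_rabs * f
        if cl:
            name = prefix + s
            sys.add_flow(ptc, name, cl / V[name])
            sys.add_flow(name, name, -cl / V[name])

    # luminal advection: leave segment i at downstream flow x upstream conc
    _, _, down = _segment_arrays(phys)
    for k, s in enumerate(segs):
        q = down[k]
        sys.add_flow(s, s, -q / V[s])
        target = segs[k + 1] if k + 1 < len(segs) else urine
        sys.add_flow(target, s, q / V[s])


def build_victim_system(cfg: ModelConfig) -> LinearSystem:
    """Assemble the joint parent+metabolite whole-body linear system."""
    phys = cfg.physiology
    compounds = [cfg.parent] + ([cfg.metabolite] if cfg.metabolite else [])
    names, volumes = [], {}
    seg_vol = phys.segment_volumes()
    for cname in compounds:
        p = cname + "."
        for comp in VICTIM_COMPARTMENTS:
            names.append(p + comp)
            if comp in ("urine", "sink", "cum_filtered", "cum_secreted"):
                volumes[p + comp] = None
            elif comp == "venous":
                volumes[p + comp] = phys.tissue_volumes["venous_blood"]
            elif comp == "arterial":
                volumes[p + comp] = phys.tissue_volumes["arterial_blood"]
            elif comp == "GLM":
                volumes[p + comp] = phys.V_GLM
            elif comp == "RBL":
                volumes[p + comp] = phys.V_RBL
            elif comp == "PTC":
                volumes[p + comp] = phys.V_PTC
            elif comp in SEGMENTS:
                volumes[p + comp] = seg_vol[comp]
            else:
                volumes[p + comp] = phys.tissue_volumes[comp]
    sys = LinearSystem(names, volumes)

    CO = phys.cardiac_output
    for cname in compounds:
        drug = cfg.drugs[cname]
        p = cname + "."
        V = sys.volumes
        Kp = drug.Kp
        R = drug.R

        def out_coef(tissue: str) -> float:
            # emergent venous (blood) concentration per unit amount
            return R / (Kp[tissue] * V[p + tissue])

        # venous -> lung -> arterial loop
        sys.add_flow(p + "venous", p + "venous", -CO / V[p + "venous"])
        sys.add_flow(p + "lung", p + "venous", CO / V[p + "venous"])
        sys.add_flow(p + "lung", p + "lung", -CO * out_coef("lung"))
        sys.add_flow(p + "arterial", p + "lung", CO * out_coef("lung"))
        sys.add_flow(p + "arterial", p + "arterial", -CO / V[p + "arterial"])

        c_art = 1.0 / V[p + "arterial"]
        for t in _DIRECT_TISSUES:
            q = phys.tissue_flows[t]
            sys.add_flow(p + t, p + "arterial", q * c_art)
            sys.add_flow(p + t, p + t, -q * out_coef(t))
            sys.add_flow(p + "venous", p + t, q * out_coef(t))
        # splanchnic: gut and spleen drain into the liver
        for t in ("gut", "spleen"):
            q = phys.tissue_flows[t]
            sys.add_flow(p + t, p + "arterial", q * c_art)
            sys.add_flow(p + t, p + t, -q * out_coef(t))
            sys.add_flow(p + "liver", p + t, q * out_coef(t))
        sys.add_flow(p + "liver", p + "arterial", phys.Q_hepatic_artery * c_art)
        sys.add_flow(p + "liver", p + "liver", -phys.QH * out_coef("liver"))
        sys.add_flow(p + "venous", p + "liver", phys.QH * out_coef("liver"))

        # hepatic elimination on the unbound emergent venous concentration
        met_entries = [(sys.index[p + "liver"], sys.index[p + "liver"], -drug.fup / (Kp["liver"] * V[p + "liver"]))]
        if cname == cfg.parent and cfg.metabolite and drug.F_NAPA:
            f = drug.F_NAPA
            met_entries.append(
                (sys.index[cfg.metabolite + ".liver"], sys.index[p + "liver"],
                 f * drug.fup / (Kp["liver"] * V[p + "liver"])))
            met_entries.append(
                (sys.index[p + "sink"], sys.index[p + "liver"],
                 (1 - f) * drug.fup / (Kp["liver"] * V[p + "liver"])))
        else:
            met_entries.append(
                (sys.index[p + "sink"], sys.index[p + "liver"],
                 drug.fup / (Kp["liver"] * V[p + "liver"])))
        for i, j, c in met_entries:
            sys.A0[i, j] += drug.CLu_int * c
        sys.tv_patterns.append(("CLu_int", cname, drug.CLu_int, met_entries))

        _add_kidney(sys, phys, drug, p, p + "arterial", p + "venous",
                    cfg.secretion_placement, cfg.reabsorption_placement,
                    counters=True)
    return sys


def build_perpetrator_system(cfg: ModelConfig, n_peripheral: int = 2,
                             kidney: bool = True) -> LinearSystem:
    """Assemble the minimal perpetrator system (central + peripherals, CL_H
    from central, kidney attached by routing QKI through renal blood)."""
    if cfg.minimal is None or cfg.perpetrator is None:
        raise ValueError("config has no perpetrator/minimal model")
    phys, m = cfg.physiology, cfg.minimal
    drug = cfg.drugs[cfg.perpetrator]
    p = cfg.perpetrator + "."
    comps = ["central"] + [f"peripheral_{i+1}" for i in range(n_peripheral)]
    if kidney:
        comps += ["GLM", "RBL", "PTC", *SEGMENTS, "urine"]
    comps += ["sink"]
    names = [p + c for c in comps]
    seg_vol = phys.segment_volumes()
    volumes: dict[str, float | None] = {p + "central": m.VC,
                                        p + "sink": None}
    for i, v in zip(range(n_peripheral), (m.V1, m.V2)):
        volumes[p + f"peripheral_{i+1}"] = v
    if kidney:
        volumes.update({p + "GLM": phys.V_GLM, p + "RBL": phys.V_RBL,
                        p + "PTC": phys.V_PTC, p + "urine": None})
        for s in SEGMENTS:
            volumes[p + s] = seg_vol[s]
    sys = LinearSystem(names, volumes)

    cen = p + "central"
    for i, cld in zip(range(n_peripheral), (m.CLD1, m.CLD2)):
        per = p + f"peripheral_{i+1}"
        sys.add_flow(cen, cen, -cld / m.VC)
        sys.add_flow(per, cen, cld / m.VC)
        sys.add_flow(per, per, -cld / volumes[per])
        sys.add_flow(cen, per, cld / volumes[per])
    sys.add_flow(cen, cen, -m.CL_H / m.VC)
    sys.add_flow(p + "sink", cen, m.CL_H / m.VC)
    if kidney:
        # central loses QKI to the kidney (glomerular blood + filtrate)
        sys.add_flow(cen, cen, -phys.QKI / m.VC)
        _add_kidney(sys, phys, drug, p, cen, cen,
                    cfg.secretion_placement, cfg.reabsorption_placement,
                    counters=False)
    return sys


# ---------------------------------------------------------------------------
# integration

def _propagate_affine(A: np.ndarray, u: np.ndarray, x: np.ndarray,
                      h: float, cache: dict) -> np.ndarray:
    """Exact step of dx/dt = A x + u over h via an augmented exponential:
    the augmented state [x; 1] evolves under [[A, u], [0, 0]]."""
    if h == 0:
        return x.copy()
    n = A.shape[0]
    key = (round(h, 12), u.tobytes())
    if key not in cache:
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = A * h
        M[:n, n] = u * h
        cache[key] = expm(M)
    aug = np.concatenate([x, [1.0]])
    return (cache[key] @ aug)[:n]


def _bolus_vector(sys: LinearSystem, target: str, nmol: float) -> np.ndarray:
    v = np.zeros(sys.n)
    v[sys.index[target]] = nmol
    return v


@dataclass
class SimulationResult:
    """Time grid plus amounts for every compartment of every compound."""

    t: np.ndarray                      # min
    amounts: np.ndarray                # nmol, shape (n_states, n_times)
    names: list[str]
    volumes: dict[str, float | None]
    mw: dict[str, float]               # g/mol per compound
    dose_nmol: dict[str, float]
    diagnostics: dict = field(default_factory=dict)

    def _idx(self, compound: str, compartment: str) -> int:
        return self.names.index(f"{compound}.{compartment}")

    def amount(self, compound: str, compartment: str) -> np.ndarray:
        return self.amounts[self._idx(compound, compartment)]

    def concentration(self, compound: str, compartment: str = "plasma"
                      ) -> np.ndarray:
        """Concentration in ug/mL. ``'plasma'`` is arterial blood over R for
        whole-body compounds and the central compartment for the perpetrator
        (both shipped compounds have R = 1)."""
        if compartment == "plasma":
            try:
                i = self._idx(compound, "arterial")
            except ValueError:
                i = self._idx(compound, "central")
        else:
            i = self._idx(compound, compartment)
        name = self.names[i]
        vol = self.volumes[name]
        if vol is None:
            raise ValueError(f"{name} is cumulative; use amount()")
        conc_nmol_ml = np.maximum(self.amounts[i], 0.0) / vol
        return conc_nmol_ml * self.mw[compound] / 1000.0

    def urine_amount_mg(self, compound: str) -> np.ndarray:
        return (np.maximum(self.amount(compound, "urine"), 0.0)
                * self.mw[compound] / 1e6)

    def urine_pct_dose(self, compound: str, of: str | None = None) -> np.ndarray:
        """Cumulative urinary recovery as % of the administered dose (molar;
        ``of`` names the dosed compound when it differs, e.g. a metabolite's
        recovery as % of the parent dose)."""
        dose = self.dose_nmol[of or compound]
        if dose == 0:
            return np.zeros_like(self.t)
        return 100.0 * np.maximum(self.amount(compound, "urine"), 0.0) / dose

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (compound, compartment, time_min, value, unit)."""
        rows = []
        for name in self.names:
            compound, compartment = name.split(".", 1)
            vol = self.volumes[name]
            series = self.amounts[self.names.index(name)]
            if vol is None:
                vals, unit = series * self.mw[compound] / 1e6, "mg"
            else:
                vals = np.maximum(series, 0) / vol * self.mw[compound] / 1000.0
                unit = "ug/mL"
            for t, v in zip(self.t, vals):
                rows.append((compound, compartment, t, v, unit))
        return pd.DataFrame(
            rows, columns=["compound", "compartment", "time_min", "value", "unit"])


def realized_reabsorbed_fraction(res: SimulationResult, compound: str) -> float:
    """Fraction of luminal input (filtration + secretion) reabsorbed rather
    than excreted by the end of the simulation."""
    into = (res.amount(compound, "cum_filtered")[-1]
            + res.amount(compound, "cum_secreted")[-1])
    if into <= 0:
        return 0.0
    return 1.0 - res.amount(compound, "urine")[-1] / into


def total_moles(res: SimulationResult, compounds: list[str]) -> np.ndarray:
    """Total moles in body + urine + elimination sinks across compounds
    (counters excluded); constant when nothing is created or destroyed."""
    tot = np.zeros_like(res.t)
    for name in res.names:
        compound, compartment = name.split(".", 1)
        if compound in compounds and compartment not in (
                "cum_filtered", "cum_secreted"):
            tot = tot + res.amounts[res.names.index(name)]
    return tot


# ---------------------------------------------------------------------------
# simulate


def _doses_for(cfg: ModelConfig, regimen: DoseRegimen, compound: str):
    drug = cfg.drugs[compound]
    out = []
    for e in regimen.for_compound(compound):
        mw_salt = drug.MW_salt if drug.MW_salt is not None else drug.MW
        _, nmol = convert_dose(e.amount_mg, e.basis, mw_salt, drug.MW)
        out.append((e, nmol))
    return out


def _integrate_linear(sys: LinearSystem, events, t_grid, target: str,
                      rtol=None) -> np.ndarray:
    """Exact piecewise-affine propagation over dose events. ``events`` is a
    list of (DoseEvent, nmol)."""
    A = sys.A0
    x = np.zeros(sys.n)
    out = np.zeros((sys.n, len(t_grid)))
    # breakpoints: event starts and infusion ends
    bps = sorted({t_grid[0]} | {e.start for e, _ in events}
                 | {e.start + e.duration for e, _ in events if e.route == "iv_infusion"})
    bps = [b for b in bps if b <= t_grid[-1]] + [t_grid[-1]]
    cache: dict = {}
    t_cur = min(bps[0], t_grid[0])
    gi = 0
    seg_bounds = sorted(set(bps))
    for k, t_next in enumerate(seg_bounds):
        if t_next > t_cur:
            # input vector over (t_cur, t_next)
            u = np.zeros(sys.n)
            for e, nmol in events:
                if e.route == "iv_infusion" and e.start <= t_cur and \
                        t_cur < e.start + e.duration - 1e-12:
                    u[sys.index[target]] += nmol / e.duration
            while gi < len(t_grid) and t_grid[gi] <= t_next + 1e-12:
                h = t_grid[gi] - t_cur
                out[:, gi] = (_propagate_affine(A, u, x, h, cache)
                              if h > 0 else x)
                gi += 1
            x = _propagate_affine(A, u, x, t_next - t_cur, cache)
            t_cur = t_next
        for e, nmol in events:
            if e.route == "iv_bolus" and math.isclose(e.start, t_cur,
                                                      abs_tol=1e-9):
                x = x + _bolus_vector(sys, target, nmol)
    while gi < len(t_grid):  # grid points at/after the final breakpoint
        out[:, gi] = x
        gi += 1
    return out


def _integrate_rhs(cfg: ModelConfig, sys: LinearSystem, rhs, events, t_grid,
                   target: str) -> tuple[np.ndarray, dict]:
    """Adaptive (or fixed-step RK4) integration with restarts at dose events."""
    x = np.zeros(sys.n)
    out = np.zeros((sys.n, len(t_grid)))
    diag = {"nfev": 0, "method": cfg.method, "rtol": cfg.rtol, "atol": cfg.atol}
    bps = sorted({t_grid[0], t_grid[-1]} | {e.start for e, _ in events}
                 | {e.start + e.duration for e, _ in events
                    if e.route == "iv_infusion"})
    bps = [b for b in bps if t_grid[0] <= b <= t_grid[-1]]
    if bps[0] > t_grid[0]:
        bps.insert(0, t_grid[0])
    gi = 0
    for k in range(len(bps)):
        t0 = bps[k]
        for e, nmol in events:
            if e.route == "iv_bolus" and math.isclose(e.start, t0, abs_tol=1e-9):
                x = x + _bolus_vector(sys, target, nmol)
        t1 = bps[k + 1] if k + 1 < len(bps) else t_grid[-1]
        while gi < len(t_grid) and t_grid[gi] <= t0 + 1e-12:
            out[:, gi] = x
            gi += 1
        if t1 <= t0:
            continue
        u = np.zeros(sys.n)
        for e, nmol in events:
            if e.route == "iv_infusion" and e.start <= t0 + 1e-12 and \
                    t0 < e.start + e.duration - 1e-12:
                u[sys.index[target]] += nmol / e.duration

        def f(t, y):
            dy = rhs(t, y) + u
            if not np.all(np.isfinite(dy)):
                raise FloatingPointError(
                    f"non-finite derivative at t={t}: state={y}")
            return dy

        seg_eval = [t for t in t_grid if t0 + 1e-12 < t < t1 - 1e-12]
        if cfg.method == "rk4":
            samples, x = _rk4(f, x, t0, t1, cfg.rk4_step, seg_eval)
            for _tv, xv in samples:
                out[:, gi] = xv
                gi += 1
        else:
            sol = solve_ivp(f, (t0, t1), x, method="LSODA",
                            rtol=cfg.rtol, atol=cfg.atol,
                            t_eval=seg_eval or None, dense_output=True)
            if not sol.success:
                raise RuntimeError(
                    f"solver failed on [{t0}, {t1}] (rtol={cfg.rtol}, "
                    f"atol={cfg.atol}): {sol.message}; last state {x}")
            diag["nfev"] += sol.nfev
            for tv in seg_eval:
                out[:, gi] = sol.sol(tv)
                gi += 1
            x = sol.sol(t1)
    while gi < len(t_grid):
        out[:, gi] = x
        gi += 1
    return out, diag


def _rk4(f, x0, t0, t1, h, t_eval):
    """Classical fixed-step fourth-order Runge-Kutta. Returns the sampled
    interior points and the state at t1."""
    out, x, t = [], x0.copy(), t0
    targets = iter(sorted(t_eval))
    nxt = next(targets, None)
    while t < t1 - 1e-12:
        step = min(h, t1 - t)
        while nxt is not None and nxt <= t + step + 1e-12:
            out.append((nxt, _rk4_step(f, x, t, max(nxt - t, 0.0))))
            nxt = next(targets, None)
        x = _rk4_step(f, x, t, step)
        t += step
    return out, x


def _rk4_step(f, x, t, h):
    if h == 0:
        return x.copy()
    k1 = f(t, x)
    k2 = f(t + h / 2, x + h / 2 * k1)
    k3 = f(t + h / 2, x + h / 2 * k2)
    k4 = f(t + h, x + h * k3)
    return x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate(cfg: ModelConfig, regimen: DoseRegimen, t_end: float,
             t_eval: np.ndarray | None = None) -> SimulationResult:
    """Integrate the configured systems over a dosing regimen.

    Control arms (no perpetrator dose) are linear time-invariant and are
    propagated exactly by the matrix exponential. When the regimen doses the
    perpetrator, its minimal system is solved first (it is unaffected by the
    victims) and its unbound concentrations drive the victims' transport
    coefficients during a second, time-varying integration.
    """
    if t_eval is None:
        t_eval = np.linspace(max(0.0, regimen.t_start), t_end, 241)
    t_eval = np.asarray(t_eval, dtype=float)

    victims = [cfg.parent] + ([cfg.metabolite] if cfg.metabolite else [])
    vic_sys = build_victim_system(cfg)
    vic_events = []
    for c in victims:
        for e, nmol in _doses_for(cfg, regimen, c):
            vic_events.append((e, nmol, c))

    perp_events = (_doses_for(cfg, regimen, cfg.perpetrator)
                   if cfg.perpetrator else [])
    ddi = bool(perp_events)

    names, blocks, volumes = [], [], {}
    mw = {c: cfg.drugs[c].MW for c in victims}
    dose_nmol = {c: sum(n for e, n, cc in vic_events if cc == c)
                 for c in victims}

    t0 = min([t_eval[0]] + [e.start for e, _, _ in vic_events]
             + [e.start for e, _ in perp_events])
    full_grid = t_eval if t_eval[0] <= t0 else np.concatenate([[t0], t_eval])
    keep = np.isin(full_grid, t_eval)

    diagnostics: dict = {}
    perp_sol = None
    if ddi:
        perp_sys = build_perpetrator_system(cfg)

        # perpetrator is linear and unaffected by the victims: solve once
        def perp_rhs(t, y):
            return perp_sys.A0 @ y

        px = np.zeros(perp_sys.n)
        bps = sorted({t0, t_end} | {e.start for e, _ in perp_events})
        segs = []
        for k, ts in enumerate(bps):
            for e, nmol in perp_events:
                if e.route == "iv_bolus" and math.isclose(e.start, ts, abs_tol=1e-9):
                    px = px + _bolus_vector(perp_sys, cfg.perpetrator + ".central", nmol)
            te = bps[k + 1] if k + 1 < len(bps) else t_end
            if te > ts:
                sol = solve_ivp(perp_rhs, (ts, te), px, method="LSODA",
                                rtol=cfg.rtol, atol=cfg.atol, dense_output=True)
                if not sol.success:
                    raise RuntimeError(f"perpetrator solver failed: {sol.message}")
                segs.append((ts, te, sol.sol))
                px = sol.sol(te)

        def perp_state(t):
            for ts, te, f in segs:
                if ts - 1e-12 <= t <= te + 1e-12:
                    return f(min(max(t, ts), te))
            return np.zeros(perp_sys.n)

        perp_sol = (perp_sys, perp_state)

    if not ddi:
        # exact linear propagation; victims dose into their venous pool
        amounts = np.zeros((vic_sys.n, len(full_grid)))
        for c in victims:
            evs = [(e, n) for e, n, cc in vic_events if cc == c]
            if evs:
                amounts += _integrate_linear(vic_sys, evs, full_grid,
                                             c + ".venous")
        diagnostics["path"] = "linear-expm"
    else:
        perp_sys, perp_state = perp_sol
        pdrug = cfg.drugs[cfg.perpetrator]
        i_rbl = perp_sys.index[cfg.perpetrator + ".RBL"]
        i_ptc = perp_sys.index[cfg.perpetrator + ".PTC"]
        i_cen = perp_sys.index[cfg.perpetrator + ".central"]
        v_rbl = perp_sys.volumes[cfg.perpetrator + ".RBL"]
        v_ptc = perp_sys.volumes[cfg.perpetrator + ".PTC"]
        v_cen = perp_sys.volumes[cfg.perpetrator + ".central"]

        def inhibitor_conc(t):
            """Unbound perpetrator concentrations (uM) driving OCT2/MATE1."""
            y = perp_state(t)
            if cfg.oct2_driver == "renal_blood":
                cu_oct2 = max(y[i_rbl], 0) / v_rbl * pdrug.fup / pdrug.R
            else:
                cu_oct2 = max(y[i_cen], 0) / v_cen * pdrug.fup / pdrug.R
            cu_mate1 = max(y[i_ptc], 0) / v_ptc * pdrug.fu_kidney
            return cu_oct2, cu_mate1

        def vic_rhs(t, y):
            cu_oct2, cu_mate1 = inhibitor_conc(t)
            scale = {}
            for c in victims:
                d = cfg.drugs[c]
                ps_in, clu = apply_inhibition(
                    d.PS_in, d.PS_out, d.CLu_int_r, cu_oct2, cu_mate1,
                    pdrug.Ki_OCT2, pdrug.Ki_MATE1)
                scale[("PS_in", c)] = ps_in
                scale[("CLu_int_r", c)] = clu
                if cfg.inhibit_metabolism and pdrug.IC50_metab and \
                        c == cfg.parent:
                    y_cen = perp_state(t)[i_cen]
                    cu_pl = max(y_cen, 0) / v_cen * pdrug.fup / pdrug.R
                    scale[("CLu_int", c)] = d.CLu_int / (1 + cu_pl / pdrug.IC50_metab)
            return vic_sys.rhs_matrix(scale) @ y

        # victims dose into their own venous pool; superpose per compound
        amounts = np.zeros((vic_sys.n, len(full_grid)))
        for c in victims:
            cevs = [(e, n) for e, n, cc in vic_events if cc == c]
            if cevs:
                a, diag = _integrate_rhs(cfg, vic_sys, vic_rhs, cevs,
                                         full_grid, c + ".venous")
                amounts += a
                diagnostics.update(diag)
        diagnostics["path"] = ("ddi-rk4" if cfg.method == "rk4"
                               else "ddi-lsoda")

    names = list(vic_sys.names)
    volumes = dict(vic_sys.volumes)
    all_amounts = amounts

    if ddi:
        perp_sys, perp_state = perp_sol
        pa = np.stack([perp_state(t) for t in full_grid], axis=1)
        all_amounts = np.vstack([amounts, pa])
        names += perp_sys.names
        volumes.update(perp_sys.volumes)
        mw[cfg.perpetrator] = cfg.drugs[cfg.perpetrator].MW
        dose_nmol[cfg.perpetrator] = sum(n for _, n in perp_events)

    return SimulationResult(
        t=full_grid[keep], amounts=all_amounts[:, keep], names=names,
        volumes=volumes, mw=mw, dose_nmol=dose_nmol,
        diagnostics=diagnostics)
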