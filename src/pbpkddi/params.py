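"""Parameter containers and the default rat parameter registry.

Houses the physiological constants of a ~250 g rat (tissue volumes and blood
flows, nephron-segment luminal flows as fractions of GFR), per-compound drug
parameters (binding, partition, renal transport, elimination), the fitted
minimal-model distribution parameters of the perpetrator, dosing regimens,
and the unit/salt conversions used throughout the package.

Conventions
-----------
* Internal amounts are molar (nmol) so that parent-to-metabolite conversion
  conserves moles; user-facing masses are mg and concentrations ug/mL.
* Volumes are mL, flows mL/min, times min.
* Doses are interpreted as the salt form unless flagged otherwise; reported
  concentrations are base-equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import yaml

__all__ = [
    "PhysiologyParams",
    "DrugParams",
    "MinimalPBPKParams",
    "DoseEvent",
    "DoseRegimen",
    "default_rat_parameters",
    "convert_dose",
    "per_kg_to_absolute",
    "save_params",
    "load_physiology",
    "load_drug",
    "REFERENCE_BW_KG",
]

#: Reference body weight (kg). The registry's absolute volumes/flows describe
#: a ~250 g rat; per-kg <-> absolute conversions use this constant unless a
#: different BW is supplied.
REFERENCE_BW_KG = 0.25

# Whole-body tissues with perfusion-limited balances. The kidney is handled
# by the semi-mechanistic submodel and is deliberately absent here.
TISSUES = (
    "adipose", "bone", "brain", "gut", "heart",
    "liver", "lung", "muscle", "skin", "spleen",
)

# Nephron luminal segments, upstream to downstream.
SEGMENTS = ("S1_1", "S1_2", "S1_3", "S2S3", "LOH", "DTCD")
PROXIMAL_SEGMENTS = ("S1_1", "S1_2", "S1_3", "S2S3")


@dataclass
class PhysiologyParams:
    """Whole-body and kidney physiology of the reference rat.

    ``tissue_flows['lung']`` is the cardiac output; after construction it is
    set to the total venous return so that flow closure holds exactly (the
    serial-liver convention: gut and spleen drain through the liver, whose
    total inflow/outflow is ``tissue_flows['liver']``).
    """

    tissue_volumes: dict[str, float]
    tissue_flows: dict[str, float]
    QKI: float          # renal blood flow (mL/min)
    GFR: float          # glomerular filtration rate (mL/min)
    V_GLM: float        # glomerular blood volume (mL)
    V_PTC: float        # proximal tubule cell volume (mL)
    V_RBL: float        # renal blood volume (mL)
    segment_flow_fractions: dict[str, float] = field(default_factory=dict)
    urine_flow_fraction: float = 0.02
    BW: float = REFERENCE_BW_KG

    def __post_init__(self) -> None:
        if not self.segment_flow_fractions:
            self.segment_flow_fractions = {
                "S1_1": 1.00, "S1_2": 0.85, "S1_3": 0.70,
                "S2S3": 0.55, "LOH": 0.33, "DTCD": 0.18,
            }
        # enforce cardiac-output closure: lung flow = venous return
        self.tissue_flows = dict(self.tissue_flows)
        self.tissue_flows["lung"] = self.cardiac_output
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def QH(self) -> float:
        """Total hepatic blood flow (liver + gut + spleen inflow)."""
        return self.tissue_flows["liver"]

    @property
    def Q_hepatic_artery(self) -> float:
        return (self.tissue_flows["liver"] - self.tissue_flows["gut"]
                - self.tissue_flows["spleen"])

    @property
    def cardiac_output(self) -> float:
        """Venous return: directly-draining tissues + liver total + kidney."""
        direct = sum(self.tissue_flows[t] for t in TISSUES
                     if t not in ("lung", "gut", "spleen"))
        return direct + self.QKI

    def segment_flows(self) -> dict[str, float]:
        """Luminal filtrate flow per segment (mL/min)."""
        return {s: f * self.GFR for s, f in self.segment_flow_fractions.items()}

    def segment_volumes(self) -> dict[str, float]:
        """Luminal volume per segment (mL); numerically fraction x GFR."""
        return {s: f * self.GFR for s, f in self.segment_flow_fractions.items()}

    @property
    def Q_urine(self) -> float:
        return self.urine_flow_fraction * self.GFR

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for name, v in {**self.tissue_volumes, "V_GLM": self.V_GLM,
                        "V_PTC": self.V_PTC, "V_RBL": self.V_RBL}.items():
            if v <= 0:
                raise ValueError(f"volume {name!r} must be positive, got {v}")
        for name, q in self.tissue_flows.items():
            if q <= 0:
                raise ValueError(f"flow {name!r} must be positive, got {q}")
        if self.QKI <= 0 or self.GFR <= 0 or self.BW <= 0:
            raise ValueError("QKI, GFR and BW must be positive")
        fracs = [self.segment_flow_fractions[s] for s in SEGMENTS]
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("segment flow fractions must strictly decrease "
                             "along the nephron")
        if not (0 < self.urine_flow_fraction < fracs[-1]):
            raise ValueError("urine flow fraction must lie below the last "
                             "segment fraction")
        if not math.isclose(self.tissue_flows["lung"], self.cardiac_output,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("cardiac output closure violated")


@dataclass
class DrugParams:
    """Per-compound physicochemical, binding, transport and elimination
    parameters.

    Transporter inhibition constants (``Ki_OCT2``/``Ki_MATE1``, uM) are set
    on perpetrators only; ``F_NAPA`` (metabolite formation fraction) on the
    parent victim only.
    """

    name: str
    MW: float                       # g/mol (base)
    fup: float                      # unbound fraction in plasma
    R: float = 1.0                  # blood-to-plasma concentration ratio
    MW_salt: float | None = None    # g/mol of the dosed salt, if any
    pKa: float | None = None
    logP: float | None = None
    Kp: dict[str, float] = field(default_factory=dict)
    fu_kidney: float | None = None
    fu_liver: float | None = None
    CLu_int: float = 0.0            # hepatic unbound intrinsic CL (mL/min)
    CLu_int_r: float = 0.0          # renal secretory unbound intrinsic CL
    PS_in: float = 0.0              # basolateral uptake clearance (mL/min)
    PS_out: float = 0.0             # basolateral efflux clearance (mL/min)
    CL_rabs: float = 0.0            # luminal reabsorption clearance (mL/min)
    Fr: float | None = None         # descriptive reabsorbed-fraction target
    F_NAPA: float | None = None     # metabolite formation fraction (parent)
    Ki_OCT2: float | None = None    # uM
    Ki_MATE1: float | None = None   # uM
    IC50_metab: float | None = None # uM, metabolic inhibition (perpetrator)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def salt_factor(self) -> float:
        """Dose-mass of salt per mass of base (1.0 for an unsalted drug)."""
        return 1.0 if self.MW_salt is None else self.MW_salt / self.MW

    def validate(self) -> None:
        if not (0 < self.fup <= 1):
            raise ValueError(f"{self.name}: fup must be in (0, 1]")
        if self.R <= 0:
            raise ValueError(f"{self.name}: R must be positive")
        for attr in ("CLu_int", "CLu_int_r", "PS_in", "PS_out", "CL_rabs"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")
        if self.F_NAPA is not None and not (0 <= self.F_NAPA <= 1):
            raise ValueError(f"{self.name}: F_NAPA must be in [0, 1]")
        for attr in ("fu_kidney", "fu_liver"):
            v = getattr(self, attr)
            if v is not None and not (0 < v <= 1):
                raise ValueError(f"{self.name}: {attr} must be in (0, 1]")
        if any(kp <= 0 for kp in self.Kp.values()):
            raise ValueError(f"{self.name}: Kp values must be positive")

    def renal_submodel_active(self) -> bool:
        return self.PS_out > 0

    def with_(self, **kw) -> "DrugParams":
        return replace(self, **kw)


@dataclass
class MinimalPBPKParams:
    """Fitted central + two-peripheral distribution model of the perpetrator."""

    VC: float    # central volume (mL)
    V1: float    # first peripheral volume (mL)
    V2: float    # second peripheral volume (mL)
    CLD1: float  # central<->P1 distributional clearance (mL/min)
    CLD2: float  # central<->P2 distributional clearance (mL/min)
    CL_H: float  # non-renal clearance from central (mL/min)

    def __post_init__(self) -> None:
        for k, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"minimal-model parameter {k} must be positive")


@dataclass(frozen=True)
class DoseEvent:
    compound: str
    route: str                # 'iv_bolus' | 'iv_infusion'
    amount_mg: float
    basis: str = "salt"       # 'salt' | 'base'
    start: float = 0.0        # min; negative = pre-dose
    duration: float = 0.0     # min, infusions only

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "iv_infusion"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.basis not in ("salt", "base"):
            raise ValueError(f"unknown dose basis {self.basis!r}")
        if self.amount_mg < 0:
            raise ValueError("dose amount must be >= 0")
        if self.route == "iv_infusion" and self.duration <= 0:
            raise ValueError("infusion duration must be positive")


@dataclass
class DoseRegimen:
    events: list[DoseEvent]

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start)

    @property
    def t_start(self) -> float:
        return min((e.start for e in self.events), default=0.0)

    def for_compound(self, name: str) -> list[DoseEvent]:
        return [e for e in self.events if e.compound == name]


# ---------------------------------------------------------------------------
# conversions

def convert_dose(amount_mg: float, basis: str, MW_salt: float,
                 MW_base: float) -> tuple[float, float]:
    """Convert a dose to (mg of base, nmol).

    ``basis='salt'`` interprets ``amount_mg`` as the salt mass (e.g. the HCl
    salt of procainamide, 271.79 g/mol dosed, 235.33 g/mol as base).
    """
    if amount_mg < 0:
        raise ValueError("dose amount must be >= 0")
    if MW_salt <= 0 or MW_base <= 0:
        raise ValueError("molecular weights must be positive")
    if basis == "salt":
        base_mg = amount_mg * MW_base / MW_salt
    elif basis == "base":
        base_mg = amount_mg
    else:
        raise ValueError(f"unknown basis {basis!r}")
    nmol = base_mg / MW_base * 1e6
    return base_mg, nmol


def per_kg_to_absolute(value: float, BW: float = REFERENCE_BW_KG) -> float:
    """Scale a per-kg clearance (mL/min/kg) or volume (mL/kg) to absolute."""
    if BW <= 0:
        raise ValueError("BW must be positive")
    return value * BW


# ---------------------------------------------------------------------------
# default registry

#: Back-solved effective tubule surface area per g kidney (cm^2/g), chosen so
#: procainamide's PAMPA permeability 0.310e-6 cm/s maps to PSout = 7.61
#: mL/min for the 1.03 g proximal-tubule-cell compartment. DERIVED constant:
#: the underlying literature value is not printed; the same constant must
#: reproduce cimetidine's PSout = 74.1 mL/min from 3.02e-6 cm/s (it does,
#: within 0.05%).
SEFF_PER_G_KIDNEY = 7.61 / (0.310e-6 * 60.0 * 1.03)


def default_rat_parameters() -> tuple[
        PhysiologyParams, dict[str, DrugParams], MinimalPBPKParams]:
    """The shipped rat parameter set for procainamide (PA), its metabolite
    N-acetylprocainamide (NAPA), and the perpetrator cimetidine.

    Partition coefficients for tissues without a measured steady-state ratio
    (adipose, bone, gut, muscle, skin) are predicted at call time with the
    Rodgers-Rowland method from the shipped rat tissue-composition table.
    """
    phys = PhysiologyParams(
        tissue_volumes={
            "adipose": 16.7, "bone": 15.7, "brain": 1.24, "gut": 6.19,
            "heart": 1.05, "liver": 8.57, "lung": 1.24, "muscle": 116.0,
            "skin": 39.4, "spleen": 0.57,
            "venous_blood": 10.2, "arterial_blood": 5.11,
        },
        tissue_flows={
            "adipose": 4.72, "bone": 8.08, "brain": 1.12, "gut": 8.08,
            "heart": 3.2, "liver": 19.4, "lung": 80.0, "muscle": 19.0,
            "skin": 4.08, "spleen": 0.88,
        },
        QKI=11.6, GFR=1.31, V_GLM=0.08, V_PTC=1.03, V_RBL=0.375,
    )

    pa = DrugParams(
        name="PA", MW=235.33, MW_salt=271.79, fup=0.870, R=1.0,
        pKa=9.04, logP=0.83,
        Kp={"kidney": 8.31, "liver": 11.7, "brain": 0.200, "heart": 3.45,
            "lung": 2.52, "spleen": 1.34},
        fu_kidney=0.223,
        CLu_int=69.0, CLu_int_r=4.67, PS_in=16.2, PS_out=7.61,
        CL_rabs=0.415, Fr=0.490, F_NAPA=0.534,
    )
    napa = DrugParams(
        name="NAPA", MW=277.36, fup=0.688, R=1.0,
        pKa=9.04, logP=0.93,
        Kp={"kidney": 31.2, "liver": 19.6, "brain": 0.713, "heart": 12.7,
            "lung": 9.68, "spleen": 7.60},
        fu_kidney=0.0588,
        CLu_int=2.88, CLu_int_r=9.16, PS_in=20.3, PS_out=7.61,
        CL_rabs=0.415, Fr=0.490,
    )
    cim = DrugParams(
        name="cimetidine", MW=252.34, fup=0.836, R=1.0,
        pKa=6.9, logP=0.48,
        Kp={"kidney": 10.3},
        fu_kidney=0.918,
        CLu_int_r=0.140, PS_in=839.0, PS_out=74.1, CL_rabs=0.0,
        Ki_OCT2=9.4, Ki_MATE1=3.01, IC50_metab=2060.0,
    )
    minimal = MinimalPBPKParams(VC=83.7, V1=125.0, V2=200.0,
                                CLD1=17.6, CLD2=2.96, CL_H=2.79)

    # fill unmeasured tissue partition coefficients by prediction
    from .partition import predict_kp_rodgers_rowland
    for drug in (pa, napa):
        pred, _fu = predict_kp_rodgers_rowland(
            pKa=drug.pKa, logP=drug.logP, fup=drug.fup, R=drug.R)
        for tissue in ("adipose", "bone", "gut", "muscle", "skin"):
            drug.Kp.setdefault(tissue, pred[tissue])

    return phys, {"PA": pa, "NAPA": napa, "cimetidine": cim}, minimal


# ---------------------------------------------------------------------------
# config file I/O

_EXPECTED_UNITS = {
    "volumes": "mL", "flows": "mL/min", "clearances": "mL/min",
    "amounts": "mg", "concentrations": "ug/mL", "Ki": "uM", "BW": "kg",
}


def save_params(obj, path) -> None:
    """Write a parameter container to YAML with a declared-units block."""
    payload = {"units": dict(_EXPECTED_UNITS),
               "kind": type(obj).__name__,
               "values": asdict(obj)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _load(path, kind: str) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if payload.get("kind") != kind:
        raise ValueError(f"{path}: expected a {kind} file, "
                         f"got {payload.get('kind')!r}")
    units = payload.get("units")
    if units is None:
        raise ValueError(f"{path}: units block is required")
    for key, expected in _EXPECTED_UNITS.items():
        if key in units and units[key] != expected:
            raise ValueError(
                f"{path}: unit {units[key]!r} for {key!r}; this registry is "
                f"defined in {expected!r}")
    return payload["values"]


def load_physiology(path) -> PhysiologyParams:
    return PhysiologyParams(**_load(path, "PhysiologyParams"))


def load_drug(path) -> DrugParams:
    return DrugParams(**_load(path, "DrugParams"))
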