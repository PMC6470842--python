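import math

import pytest
from hypothesis import given, settings, strategies as st

from pbpkddi.params import (DoseEvent, DrugParams, PhysiologyParams,
                            convert_dose, default_rat_parameters,
                            load_drug, load_physiology, per_kg_to_absolute,
                            save_params, SEGMENTS)


def test_cardiac_output_closure(registry):
    phys, _, _ = registry
    # lung flow is forced to the venous return, not the raw printed value
    assert phys.tissue_flows["lung"] == pytest.approx(phys.cardiac_output)
    direct = sum(phys.tissue_flows[t] for t in
                 ("adipose", "bone", "brain", "heart", "muscle", "skin"))
    assert phys.cardiac_output == pytest.approx(direct + phys.QH + phys.QKI)


def test_hepatic_flow_split(registry):
    phys, _, _ = registry
    assert phys.QH == pytest.approx(19.4)
    assert phys.Q_hepatic_artery == pytest.approx(19.4 - 8.08 - 0.88)


def test_segment_flows_decrease(registry):
    phys, _, _ = registry
    flows = [phys.segment_flows()[s] for s in SEGMENTS]
    assert all(a > b for a, b in zip(flows, flows[1:]))
    assert phys.Q_urine < flows[-1]


def test_salt_dose_conversion():
    base_mg, nmol = convert_dose(2.5, "salt", 271.79, 235.33)
    assert base_mg == pytest.approx(2.5 * 235.33 / 271.79)
    assert nmol == pytest.approx(base_mg / 235.33 * 1e6)
    same_mg, _ = convert_dose(base_mg, "base", 271.79, 235.33)
    assert same_mg == pytest.approx(base_mg)


@given(st.floats(0.001, 1e3), st.floats(100.0, 400.0), st.floats(1.0, 2.0))
@settings(max_examples=50, deadline=None)
def test_dose_round_trip(amount, mw_base, salt_ratio):
    mw_salt = mw_base * salt_ratio
    base_mg, nmol = convert_dose(amount, "salt", mw_salt, mw_base)
    # converting the base-equivalent mass back to moles is consistent
    base2, nmol2 = convert_dose(base_mg, "base", mw_salt, mw_base)
    assert math.isclose(nmol, nmol2, rel_tol=1e-12)
    assert math.isclose(base_mg * salt_ratio, amount, rel_tol=1e-12)


def test_per_kg_scaling():
    assert per_kg_to_absolute(73.3, 0.25) == pytest.approx(18.325)
    with pytest.raises(ValueError):
        per_kg_to_absolute(1.0, 0.0)


def test_drug_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        DrugParams(name="x", MW=100.0, fup=1.5)
    with pytest.raises(ValueError):
        DrugParams(name="x", MW=100.0, fup=0.5, CLu_int=-1.0)
    with pytest.raises(ValueError):
        DrugParams(name="x", MW=100.0, fup=0.5, Kp={"liver": -2.0})


def test_dose_event_validation():
    with pytest.raises(ValueError):
        DoseEvent("PA", "oral", 1.0)
    with pytest.raises(ValueError):
        DoseEvent("PA", "iv_infusion", 1.0, duration=0.0)
    with pytest.raises(ValueError):
        DoseEvent("PA", "iv_bolus", -1.0)


def test_physiology_rejects_nonmonotone_segments(registry):
    phys, _, _ = registry
    bad = dict(phys.segment_flow_fractions)
    bad["LOH"] = 0.9
    with pytest.raises(ValueError):
        PhysiologyParams(
            tissue_volumes=phys.tissue_volumes,
            tissue_flows=dict(phys.tissue_flows), QKI=phys.QKI,
            GFR=phys.GFR, V_GLM=phys.V_GLM, V_PTC=phys.V_PTC,
            V_RBL=phys.V_RBL, segment_flow_fractions=bad)


def test_yaml_round_trip(tmp_path, registry):
    phys, drugs, _ = registry
    p = tmp_path / "phys.yaml"
    save_params(phys, p)
    phys2 = load_physiology(p)
    assert phys2.tissue_flows == phys.tissue_flows
    d = tmp_path / "pa.yaml"
    save_params(drugs["PA"], d)
    pa2 = load_drug(d)
    assert pa2.CLu_int_r == drugs["PA"].CLu_int_r
    assert pa2.Kp == drugs["PA"].Kp


def test_yaml_units_enforced(tmp_path, registry):
    phys, _, _ = registry
    p = tmp_path / "phys.yaml"
    save_params(phys, p)
    text = p.read_text().replace("mL/min", "L/h")
    p.write_text(text)
    with pytest.raises(ValueError, match="unit"):
        load_physiology(p)


def test_default_registry_complete():
    phys, drugs, minimal = default_rat_parameters()
    body_tissues = set(phys.tissue_volumes) - {"venous_blood",
                                               "arterial_blood"}
    for name in ("PA", "NAPA"):
        # every perfusion-limited tissue has a partition coefficient
        assert body_tissues <= set(drugs[name].Kp)
    assert minimal.VC == pytest.approx(83.7)
    assert drugs["cimetidine"].Ki_MATE1 == pytest.approx(3.01)
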