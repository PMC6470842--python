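import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbpkddi.nca import (ConcentrationTimeProfile, UrineCollection,
                         auc_trapezoid, lambda_z, renal_clearance, summarize)

K_GEN = 0.0137  # generating mono-exponential rate constant (1/min)


def _mono_profile(k=K_GEN, c0=10.0, dose_mg=2.0):
    t = np.array([1, 5, 15, 30, 60, 120, 180, 240, 360, 480.0])
    return ConcentrationTimeProfile(t, c0 * np.exp(-k * t), dose_mg)


def test_lambda_z_exact_monoexponential():
    lz, n, adj = lambda_z(_mono_profile())
    assert lz == pytest.approx(K_GEN, rel=1e-10)
    assert adj == pytest.approx(1.0, abs=1e-10)
    res = summarize(_mono_profile())
    assert res.t_half == pytest.approx(math.log(2) / K_GEN, rel=1e-10)
    assert res.t_half == pytest.approx(50.4, rel=5e-3)


def test_log_trapezoid_exact_on_exponential():
    """The log rule integrates an exponential segment exactly."""
    t = np.array([0.0, 10.0, 50.0, 200.0])
    c = 8.0 * np.exp(-0.02 * t)
    auc, aumc = auc_trapezoid(t, c)
    exact_auc = 8.0 / 0.02 * (1 - math.exp(-0.02 * 200))
    assert auc == pytest.approx(exact_auc, rel=1e-12)


def test_monoexponential_full_nca():
    res = summarize(_mono_profile())
    c0, k, dose = 10.0, K_GEN, 2.0
    # AUCinf = C0/k minus the unobserved 0-1 min area
    exact = c0 / k - c0 / k * (1 - math.exp(-k * 1.0))
    assert res.AUC_inf == pytest.approx(exact, rel=1e-10)
    assert res.CL == pytest.approx(dose * 1000 / 0.25 / exact, rel=1e-10)
    assert res.MRT > 0 and res.Vss == pytest.approx(res.CL * res.MRT)


def test_linear_rule_on_rising_limb():
    t = np.array([0.0, 1.0, 2.0])
    c = np.array([0.0, 4.0, 2.0])
    auc, _ = auc_trapezoid(t, c)
    rising = 0.5 * 4.0
    falling = (4.0 - 2.0) / math.log(2.0)
    assert auc == pytest.approx(rising + falling, rel=1e-12)


@given(st.lists(st.floats(0.1, 100.0), min_size=4, max_size=10),
       st.floats(1.0, 20.0))
@settings(max_examples=100, deadline=None)
def test_auc_additivity(concs, dt):
    """AUC over a partition equals the sum of the pieces."""
    t = np.arange(len(concs), dtype=float) * dt
    c = np.array(concs)
    total, _ = auc_trapezoid(t, c)
    mid = len(concs) // 2
    left, _ = auc_trapezoid(t[:mid + 1], c[:mid + 1])
    right, _ = auc_trapezoid(t[mid:], c[mid:])
    assert math.isclose(total, left + right, rel_tol=1e-10)


def test_lambda_z_excludes_cmax():
    t = np.array([1, 5, 15, 30, 60, 120, 180, 240.0])
    c = np.array([1.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.25])
    lz, n, _ = lambda_z(ConcentrationTimeProfile(t, c, 1.0))
    assert n <= 6  # the Cmax point at t=5 cannot be in the window


def test_lambda_z_rejects_flat_profile():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    c = np.array([1.0, 1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        lambda_z(ConcentrationTimeProfile(t, c, 1.0))


def test_profile_validation():
    with pytest.raises(ValueError):
        ConcentrationTimeProfile([1.0, 1.0], [1.0, 2.0], 1.0)
    with pytest.raises(ValueError):
        ConcentrationTimeProfile([1.0, 2.0], [1.0, -2.0], 1.0)


def _urine(amounts_ug):
    bounds = [(0, 2), (2, 4), (4, 6), (6, 8), (8, 24)]
    return [UrineCollection(a, b, 1.0, x)
            for (a, b), x in zip(bounds, amounts_ug)]


def test_renal_clearance_definition():
    urine = _urine([100.0, 80.0, 60.0, 40.0, 20.0])
    cl_r, xe = renal_clearance(urine, AUC_inf=50.0, dose_ug_per_kg=4000.0,
                               BW=0.25)
    assert cl_r == pytest.approx(300.0 / 0.25 / 50.0)
    assert xe == pytest.approx(100 * 300.0 / 0.25 / 4000.0)


def test_renal_clearance_requires_full_coverage():
    urine = _urine([1, 1, 1, 1, 1.0])[:-1]   # stops at 8 h
    with pytest.raises(ValueError):
        renal_clearance(urine, 50.0, 4000.0)


def test_renal_clearance_rejects_gaps():
    urine = [UrineCollection(0, 2, 1.0, 1.0),
             UrineCollection(3, 24, 1.0, 1.0)]
    with pytest.raises(ValueError):
        renal_clearance(urine, 50.0, 4000.0)
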