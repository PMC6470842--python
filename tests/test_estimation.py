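import pytest

from pbpkddi.estimation import (aic, fit_clu_int_r, fit_clu_int_r_sequential,
                                fit_minimal_pbpk)
from pbpkddi.synth import NoiseModel, generate_pk_study


def test_aic_formula():
    import math
    assert aic(10.0, 20, 3) == pytest.approx(20 * math.log(0.5) + 6)
    with pytest.raises(ValueError):
        aic(0.0, 10, 1)


@pytest.fixture(scope="module")
def noiseless_study(cfg, control_regimen):
    return generate_pk_study(cfg, control_regimen,
                             noise=NoiseModel(cv=0.0, seed=0), n_subjects=1)


def test_fit_clu_int_r_noiseless_recovery(cfg, control_regimen,
                                          noiseless_study):
    pl = noiseless_study.plasma
    ur = noiseless_study.urine
    est = fit_clu_int_r(cfg, control_regimen, "PA",
                        pl[pl["compound"] == "PA"],
                        ur[ur["compound"] == "PA"], x0=2.0)
    assert est.value == pytest.approx(cfg.drugs["PA"].CLu_int_r, rel=1e-3)
    assert est.ssr < 1e-8


def test_fit_clu_int_r_sequential(cfg, control_regimen, noiseless_study):
    out = fit_clu_int_r_sequential(cfg, control_regimen,
                                   noiseless_study.plasma,
                                   noiseless_study.urine)
    assert out["PA"].value == pytest.approx(4.67, rel=1e-3)
    assert out["NAPA"].value == pytest.approx(9.16, rel=1e-3)


def test_fit_minimal_pbpk_noiseless_vc(cfg):
    """Three-compartment refit on its own noiseless output recovers the
    central volume to < 1%."""
    import numpy as np
    from pbpkddi.estimation import _perp_concentrations
    dose_nmol = 25.0 / 252.34 * 1e6
    t = np.array([1, 5, 15, 30, 60, 120, 240, 480, 720, 1080, 1440.0])
    mw = cfg.drugs["cimetidine"].MW
    conc = _perp_concentrations(cfg, cfg.minimal, 2, dose_nmol, t) \
        * mw / 1000.0
    fit = fit_minimal_pbpk(cfg, t, conc, dose_nmol, n_compartments=3)
    assert fit.params.VC == pytest.approx(cfg.minimal.VC, rel=0.01)
    assert fit.ssr < 1e-6


def test_minimal_variant_selection_by_aic(cfg):
    """Data generated by the three-compartment model prefers it (or at
    least fits it far better) over the one-compartment variant."""
    import numpy as np
    from pbpkddi.estimation import _perp_concentrations
    dose_nmol = 25.0 / 252.34 * 1e6
    t = np.array([1, 5, 15, 30, 60, 120, 240, 480, 720, 1080, 1440.0])
    mw = cfg.drugs["cimetidine"].MW
    conc = _perp_concentrations(cfg, cfg.minimal, 2, dose_nmol, t) \
        * mw / 1000.0
    fits = {n: fit_minimal_pbpk(cfg, t, conc, dose_nmol, n_compartments=n)
            for n in (1, 3)}
    assert fits[3].aic < fits[1].aic
    assert fits[3].ssr < fits[1].ssr


def test_fit_requires_enough_observations(cfg, control_regimen):
    import pandas as pd
    pl = pd.DataFrame({"time_min": [5.0], "conc_ug_ml": [1.0]})
    with pytest.raises(ValueError):
        fit_clu_int_r(cfg, control_regimen, "PA", pl)
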