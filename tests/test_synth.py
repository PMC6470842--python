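import numpy as np
import pytest

from pbpkddi.synth import (NoiseModel, PLASMA_TIMES_MIN, URINE_INTERVALS_H,
                           generate_pk_study)


def test_noise_model_sigma_and_cv():
    nm = NoiseModel(cv=0.20, seed=0)
    rng = nm.rng()
    x = nm.perturb(np.full(200_000, 10.0), rng)
    assert np.std(x) / np.mean(x) == pytest.approx(0.20, rel=0.02)
    # multiplicative log-normal noise is median-unbiased
    assert np.median(x) == pytest.approx(10.0, rel=0.01)


def test_noise_model_validation():
    with pytest.raises(ValueError):
        NoiseModel(cv=-0.1)
    with pytest.raises(ValueError):
        NoiseModel(cv=0.1, lloq=-1.0)


def test_study_shapes_and_design(cfg, control_regimen):
    study = generate_pk_study(cfg, control_regimen,
                              noise=NoiseModel(cv=0.2, seed=1), n_subjects=4)
    assert len(study.plasma) == 4 * 2 * len(PLASMA_TIMES_MIN)
    assert len(study.urine) == 4 * 2 * len(URINE_INTERVALS_H)
    assert set(study.plasma["compound"]) == {"PA", "NAPA"}
    assert sorted(study.plasma["time_min"].unique()) == \
        sorted(PLASMA_TIMES_MIN)
    assert study.dose_mg["PA"] == pytest.approx(2.5 * 235.33 / 271.79)


def test_study_seeded_determinism(cfg, control_regimen):
    a = generate_pk_study(cfg, control_regimen, noise=NoiseModel(0.2, seed=5))
    b = generate_pk_study(cfg, control_regimen, noise=NoiseModel(0.2, seed=5))
    c = generate_pk_study(cfg, control_regimen, noise=NoiseModel(0.2, seed=6))
    assert a.plasma.equals(b.plasma)
    assert a.urine.equals(b.urine)
    assert not a.plasma.equals(c.plasma)


def test_zero_noise_matches_truth(cfg, control_regimen):
    study = generate_pk_study(cfg, control_regimen,
                              noise=NoiseModel(cv=0.0, seed=0), n_subjects=2)
    s1 = study.plasma[study.plasma["subject"] == "rat01"]
    for compound in ("PA", "NAPA"):
        obs = s1[s1["compound"] == compound].sort_values("time_min")
        tru = study.truth_plasma[
            study.truth_plasma["compound"] == compound
        ].sort_values("time_min")
        assert np.allclose(obs["conc_ug_ml"].to_numpy(),
                           tru["conc_ug_ml"].to_numpy())
    # urine amounts reconstruct from volume x concentration
    u1 = study.urine[(study.urine["subject"] == "rat01")
                     & (study.urine["compound"] == "PA")]
    amt = (u1["volume_ml"] * u1["conc_ug_ml"] / 1000.0).to_numpy()
    tru = study.truth_urine[
        study.truth_urine["compound"] == "PA"]["amount_mg"].to_numpy()
    assert np.allclose(amt, tru)


def test_truth_urine_sums_to_simulated_total(cfg, control_regimen,
                                             control_result):
    study = generate_pk_study(cfg, control_regimen,
                              noise=NoiseModel(cv=0.0, seed=0), n_subjects=1)
    tot = study.truth_urine[
        study.truth_urine["compound"] == "PA"]["amount_mg"].sum()
    assert tot == pytest.approx(control_result.urine_amount_mg("PA")[-1],
                                rel=1e-6)
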