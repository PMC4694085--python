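"""Experiment designs, schedules, the trial generator, and CSV round trips."""

import numpy as np
import pandas as pd
import pytest

from recallmix.circular import kappa_to_sigma, sigma_to_kappa
from recallmix.datasets import (Dataset, ExperimentDesign, GenParams,
                                SchemaError, experiment_design,
                                generate_experiment, read_dataset,
                                trial_schedule_total, write_dataset)


def test_color_only_schedule_sums_to_stated_total():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error")
        assert trial_schedule_total(experiment_design("e4")) == 6800.0


def test_probe_schedule_component_sum_flags_discrepancy():
    """The enumerated probe-trial events sum to 7400 ms while the stated
    total is 7800 ms; the component sum is reported and the gap flagged."""
    with pytest.warns(RuntimeWarning, match="differs from the component sum"):
        assert trial_schedule_total(experiment_design("e1")) == 7400.0


def test_empty_schedule_and_negative_duration():
    d = experiment_design("e4", event_durations_ms=(), stated_total_ms=None)
    assert trial_schedule_total(d) == 0.0
    bad = experiment_design("e4", event_durations_ms=(("x", -5),),
                            stated_total_ms=None)
    with pytest.raises(ValueError):
        trial_schedule_total(bad)


def test_design_invariants():
    with pytest.raises(ValueError):
        ExperimentDesign("bad", 5, 10, 10, 5, 0.5, "color_only", True, False)
    with pytest.raises(ValueError):
        experiment_design("nope")


def test_e4_counts_per_participant(e4_dataset):
    study = e4_dataset.study()
    per = study.groupby(["participant", "item_type"], observed=True).size()
    assert set(per) == {60}
    assert len(study) == 33 * 120
    # no probes, no foils, no recognition report
    assert not study["probe_present"].any()
    assert (e4_dataset.test()["recognition_response"] == "none").all()
    assert (e4_dataset.test()["item_type"] != "foil").all()


def test_e1_counts_and_probes(e1_dataset):
    study = e1_dataset.study()
    per = study.groupby(["participant", "item_type"], observed=True).size()
    assert set(per) == {15}
    probes = study.groupby(["participant", "item_type"], observed=True)["probe_present"].sum()
    assert set(probes) == {11}  # 11 probe + 4 catch per instruction
    test = e1_dataset.test()
    assert (test.groupby("participant").size() == 60).all()
    assert test["recognition_response"].isin(["old", "new"]).all()


def test_generator_deterministic():
    d = experiment_design("e2")
    a = generate_experiment(d, GenParams(), seed=77).records
    b = generate_experiment(d, GenParams(), seed=77).records
    pd.testing.assert_frame_equal(a, b)
    c = generate_experiment(d, GenParams(), seed=78).records
    assert not a.equals(c)


def test_foil_invariants(e1_dataset):
    test = e1_dataset.test()
    foils = test[test.item_type == "foil"]
    assert foils["studied_color"].isna().all()
    assert foils["signed_error"].isna().all()


def test_pure_guessing_gives_chance_error():
    params = GenParams(rho_R=0.0, rho_F=0.0, seed=None)
    ds = generate_experiment(experiment_design("e4"), params, seed=5)
    err = np.abs(ds.test()["signed_error"].dropna())
    # 3960 uniform guesses: SE of the mean ~ 0.8 deg
    assert err.mean() == pytest.approx(90.0, abs=2.5)


def test_mixture_identity_mean_absolute_error():
    """Empirical mean |error| ~ rho E|vM(kappa)| + (1 - rho) * 90."""
    from recallmix.circular import sample_von_mises

    params = GenParams(rho_R=0.6, rho_F=0.6, sigma_R_deg=30.0, sigma_F_deg=30.0,
                       vp_spread=0.0, ranef_sd_rho=0.0, ranef_sd_logkappa=0.0)
    big = experiment_design("e4", n_participants=60)
    ds = generate_experiment(big, params, seed=9)
    err = np.abs(ds.test()["signed_error"].dropna().to_numpy())
    kappa = sigma_to_kappa(30.0)
    e_vm = np.abs(sample_von_mises(kappa, 200_000, rng=3)).mean()
    expected = 0.6 * e_vm + 0.4 * 90.0
    assert err.mean() == pytest.approx(expected, abs=1.5)


def test_memory_component_circular_sd_matches_sigma():
    """With homogeneous participants and rho = 1 the empirical circular SD
    of the errors matches the generative sigma."""
    from recallmix.circular import circular_sd_deg

    params = GenParams(rho_R=1.0, rho_F=1.0, sigma_R_deg=30.0, sigma_F_deg=30.0,
                       vp_spread=0.0, ranef_sd_rho=0.0, ranef_sd_logkappa=0.0)
    ds = generate_experiment(experiment_design("e4", n_participants=80), params, seed=10)
    err = ds.test()["signed_error"].dropna().to_numpy()
    assert circular_sd_deg(err) == pytest.approx(30.0, abs=1.0)


def test_foil_old_rate_approaches_inverse_logit_intercept():
    from scipy.special import expit

    d = experiment_design("e1", n_participants=200)
    ds = generate_experiment(d, GenParams(), seed=123)
    test = ds.test()
    foils = test[test.item_type == "foil"]
    rate = (foils["recognition_response"] == "old").mean()
    # participant logit-normal intercepts: compare against the marginal rate
    u = np.random.default_rng(0).normal(0, 0.5, 400_000)
    marginal = expit(-0.39 + u).mean()
    assert rate == pytest.approx(marginal, abs=0.02)


def test_rkn_protocol_levels():
    ds = generate_experiment(experiment_design("e3"), GenParams(), seed=6)
    resp = ds.test()["recognition_response"]
    assert set(resp) <= {"remember", "know", "no"}


def test_csv_round_trip(tmp_path, e1_dataset):
    path = tmp_path / "e1.csv"
    write_dataset(e1_dataset, path)
    back = read_dataset(path)
    pd.testing.assert_frame_equal(
        e1_dataset.records.reset_index(drop=True), back.records,
        check_exact=False, atol=1e-6)
    assert back.design == e1_dataset.design
    assert back.truth == e1_dataset.truth


def test_schema_errors(tmp_path, e4_dataset):
    df = e4_dataset.records.copy()
    path = tmp_path / "bad.csv"
    df.drop(columns=["item_type"]).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="item_type"):
        read_dataset(path)
    df2 = e4_dataset.records.copy()
    df2.loc[df2.index[0], "studied_color"] = 370.0
    df2.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="studied_color"):
        read_dataset(path)


def test_genparams_validation():
    with pytest.raises(ValueError):
        GenParams(rho_R=1.5)
    with pytest.raises(ValueError):
        GenParams(sigma_F_deg=-1)
    with pytest.raises(ValueError):
        GenParams(vp_spread=-0.1)


def test_sigma_kappa_defaults_consistent():
    p = GenParams()
    assert kappa_to_sigma(p.kappa("R")) == pytest.approx(p.sigma_R_deg, abs=1e-6)
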