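"""Hierarchical regression models: trivial cases, scales, and contrasts.

Fits here use reduced sampler settings on small synthetic tables; parameter
recovery at the published experiment scales lives in the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

from recallmix.circular import kappa_to_sigma, sample_von_mises
from recallmix.glm import (AbsoluteErrorModel, LogRtModel, MultilevelLogistic,
                           VonMisesDispersionModel, contrast)

from conftest import make_trials

FAST = dict(n_steps=500)


@pytest.fixture(scope="module")
def coin_flip_fit():
    """Intercept-only logistic data with a 50% 'old' rate."""
    rng = np.random.default_rng(21)
    n_per, n_p = 60, 10
    df = make_trials(
        participant=np.repeat(np.arange(1, n_p + 1), n_per),
        item_type=["R"] * (n_per * n_p),
        recognition_response=list(rng.choice(["old", "new"], n_per * n_p)),
    )
    return MultilevelLogistic(item_types=("R",), seed=1, **FAST).fit(df)


def test_intercept_only_logistic_near_zero(coin_flip_fit):
    assert coin_flip_fit.coefficients_["b_R"].median == pytest.approx(0.0, abs=0.15)
    lo, hi = coin_flip_fit.condition_means_["R"].hdi95
    assert lo < 0.5 < hi


def test_logistic_requires_trials_in_every_condition():
    df = make_trials(participant=[1, 1, 2, 2], item_type=["R"] * 4,
                     recognition_response=["old", "new", "old", "new"])
    with pytest.raises(ValueError, match="zero trials"):
        MultilevelLogistic(item_types=("foil", "F", "R"), seed=0).fit(df)
    with pytest.raises(ValueError, match="participants"):
        MultilevelLogistic(item_types=("R",), seed=0).fit(df[df.participant == 1])


def test_contrast_identities(coin_flip_fit):
    self_c = coin_flip_fit.contrast("R", "R")
    assert self_c.median == 0.0 and self_c.hdi95 == (0.0, 0.0)


@pytest.fixture(scope="module")
def rt_fit():
    """Log-RT model on data with a known instruction effect."""
    rng = np.random.default_rng(22)
    n_p, n_per = 12, 24
    rows = []
    for p in range(1, n_p + 1):
        u = rng.normal(0, 0.1)
        for cond, mu in (("F", 6.3), ("R", 6.15)):
            rows += [(p, cond, float(np.exp(rng.normal(mu + u, 0.2))))
                     for _ in range(n_per)]
    df = make_trials(
        participant=[r[0] for r in rows], item_type=[r[1] for r in rows],
        phase="study", probe_present=[True] * len(rows),
        probe_rt_ms=[r[2] for r in rows])
    return LogRtModel(seed=2, **FAST).fit(df)


def test_rt_model_recovers_log_means(rt_fit):
    assert rt_fit.coefficients_["intercept_F"].median == pytest.approx(6.3, abs=0.05)
    assert rt_fit.coefficients_["instruction_R"].median == pytest.approx(-0.15, abs=0.06)


def test_rt_back_transform_is_draw_wise(rt_fit):
    log_draws = rt_fit.condition_link_draws("F")
    ms_draws = rt_fit.condition_mean_draws("F")
    assert np.allclose(ms_draws, np.exp(log_draws))
    # Jensen gap: mean of exp draws exceeds exp of mean log draw
    assert ms_draws.mean() > np.exp(log_draws.mean())


def test_rt_contrast_antisymmetric(rt_fit):
    fr = rt_fit.contrast("F", "R")
    rf = rt_fit.contrast("R", "F")
    assert np.allclose(fr.draws, -rf.draws)
    assert fr.median > 0  # F slower than R in this simulation


def test_rt_constant_response_degenerate():
    df = make_trials(participant=[1, 1, 2, 2, 3, 3], item_type=["F", "R"] * 3,
                     phase="study", probe_present=[True] * 6,
                     probe_rt_ms=[500.0] * 6)
    fit = LogRtModel(seed=3, **FAST).fit(df)
    assert fit.coefficients_["intercept_F"].median == pytest.approx(np.log(500), abs=0.02)
    assert fit.coefficients_["instruction_R"].median == pytest.approx(0.0, abs=0.02)


def test_rt_interaction_cell_check():
    df = make_trials(participant=[1, 1, 2, 2], item_type=["F", "R", "F", "R"],
                     phase="study", probe_present=[True] * 4,
                     probe_rt_ms=[400.0, 420.0, 410.0, 430.0])
    with pytest.raises(ValueError, match="cell"):
        LogRtModel(with_task=True, seed=0).fit(df)  # no baseline trials


def test_proportion_contrast_is_difference_of_backtransforms(coin_flip_fit):
    """The proportion-scale contrast must be computed draw-wise on the
    back-transformed values, not by back-transforming the coefficient gap."""
    from scipy.special import expit

    fit = coin_flip_fit
    d = fit.contrast("R", "R").draws
    assert np.allclose(d, 0.0)
    # construct a two-condition check on the logistic fit machinery
    rng = np.random.default_rng(23)
    df = make_trials(
        participant=np.repeat(np.arange(1, 9), 80),
        item_type=list(np.tile(["F"] * 40 + ["R"] * 40, 8)),
        recognition_response=list(np.where(
            rng.random(640) < np.tile([0.4] * 40 + [0.7] * 40, 8), "old", "new")),
    )
    m = MultilevelLogistic(item_types=("F", "R"), seed=4, **FAST).fit(df)
    diff = m.contrast("R", "F").draws
    beta = m.draws_["b_F"], m.draws_["b_R"]
    drawwise = expit(beta[0] + beta[1]) - expit(beta[0])
    assert np.allclose(diff, drawwise)
    naive = expit(np.median(beta[0] + beta[1])) - expit(np.median(beta[0]))
    assert abs(np.mean(diff) - naive) > 1e-6


def test_absolute_error_chance_and_exact():
    rng = np.random.default_rng(24)
    n_p, n_per = 10, 30
    part = np.repeat(np.arange(1, n_p + 1), 2 * n_per)
    itypes = list(np.tile(["F"] * n_per + ["R"] * n_per, n_p))
    guess = make_trials(participant=part, item_type=itypes,
                        signed_error=list(180 - rng.uniform(0, 360, len(part))))
    fit = AbsoluteErrorModel(seed=5, **FAST).fit(guess)
    for c in ("F", "R"):
        assert fit.condition_means_[c].median == pytest.approx(90.0, abs=5.0)
    exact = make_trials(participant=part, item_type=itypes,
                        signed_error=[0.0] * len(part))
    fit0 = AbsoluteErrorModel(seed=6, **FAST).fit(exact)
    assert fit0.condition_means_["R"].median == pytest.approx(0.0, abs=0.5)


def test_absolute_error_contrast_recovery():
    """True condition means 90 (F) vs 71 (R): the F - R contrast ~ 19 deg."""
    rng = np.random.default_rng(25)
    n_p, n_per = 16, 40
    rows = []
    for p in range(1, n_p + 1):
        u = rng.normal(0, 5)
        for cond, mu in (("F", 90.0), ("R", 71.0)):
            vals = np.clip(rng.normal(mu + u, 40, n_per), 0, 180)
            rows += [(p, cond, v * rng.choice([-1, 1])) for v in vals]
    df = make_trials(participant=[r[0] for r in rows],
                     item_type=[r[1] for r in rows],
                     signed_error=[r[2] for r in rows])
    fit = AbsoluteErrorModel(seed=7, **FAST).fit(df)
    assert fit.contrast("F", "R").median == pytest.approx(19.0, abs=6.0)


def test_vonmises_dispersion_bessel_oracle():
    """Errors drawn from vM(kappa = 1) recover sigma ~ 72.8 degrees."""
    rng = np.random.default_rng(26)
    n_p, n_per = 10, 60
    part = np.repeat(np.arange(1, n_p + 1), 2 * n_per)
    itypes = list(np.tile(["F"] * n_per + ["R"] * n_per, n_p))
    errs = sample_von_mises(1.0, len(part), rng=rng)
    df = make_trials(participant=part, item_type=itypes, signed_error=list(errs))
    fit = VonMisesDispersionModel(seed=8, **FAST).fit(df)
    for c in ("F", "R"):
        lo, hi = fit.condition_means_[c].hdi95
        assert lo < kappa_to_sigma(1.0) < hi
        assert fit.condition_means_[c].median == pytest.approx(72.8, abs=4.0)


def test_vonmises_near_uniform_data():
    rng = np.random.default_rng(27)
    part = np.repeat(np.arange(1, 9), 60)
    itypes = list(np.tile(["F"] * 30 + ["R"] * 30, 8))
    errs = sample_von_mises(0.125, len(part), rng=rng)
    fit = VonMisesDispersionModel(seed=9, **FAST).fit(
        make_trials(participant=part, item_type=itypes, signed_error=list(errs)))
    assert fit.condition_means_["F"].median > 130.0
    lo, hi = fit.condition_means_["F"].hdi95
    assert hi - lo > 30.0  # wide interval: dispersion barely identified


def test_vonmises_zero_errors_hit_kappa_cap():
    part = np.repeat(np.arange(1, 6), 20)
    itypes = list(np.tile(["F"] * 10 + ["R"] * 10, 5))
    fit = VonMisesDispersionModel(seed=10, **FAST).fit(
        make_trials(participant=part, item_type=itypes,
                    signed_error=[0.0] * len(part)))
    # sigma collapses to the documented lower bound set by the kappa cap
    assert fit.condition_means_["R"].median <= kappa_to_sigma(499.0) + 0.1


def test_module_level_contrast_helper(rt_fit):
    assert contrast(rt_fit, "F", "R").median == rt_fit.contrast("F", "R").median
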