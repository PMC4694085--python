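"""Trial-exclusion and conditionalization rules."""

import numpy as np
import pandas as pd
import pytest

from recallmix.preprocess import (conditionalize_color_trials,
                                  filter_probe_rts, filter_recognition_trials,
                                  independent_know_subset)

from conftest import make_trials


def recog_table(rts, participant=None):
    n = len(rts)
    return make_trials(
        participant=participant or [1] * n,
        item_type=["R"] * n,
        recognition_rt_ms=list(rts),
        recognition_response=["old"] * n,
    )


def test_rt_floor_stage():
    df = recog_table([99.0, 100.0, 500.0, 800.0])
    rep = filter_recognition_trials(df)
    assert rep.n_rt_floor_excluded == 1
    assert 100.0 in rep.retained["recognition_rt_ms"].values  # boundary kept


def test_sd_stage_on_constructed_vector():
    """A tight log-RT cluster plus one far outlier: exactly one SD exclusion."""
    rng = np.random.default_rng(0)
    base = np.exp(rng.normal(6.5, 0.05, 100))
    out = float(np.exp(6.5 + 0.05 * 20))  # ~20 cluster SDs away
    df = recog_table(list(base) + [out])
    rep = filter_recognition_trials(df)
    assert rep.n_rt_floor_excluded == 0
    assert rep.n_sd_excluded == 1
    assert out not in rep.retained["recognition_rt_ms"].values


def test_identical_rts_no_sd_exclusions():
    rep = filter_recognition_trials(recog_table([400.0] * 20))
    assert rep.n_sd_excluded == 0
    assert rep.n_retained == 20


def test_filter_ordering_floor_before_sd():
    """Sub-floor RTs must not enter the SD computation."""
    fast = [1.0] * 30                     # would wreck the pooled log-RT SD
    normal = np.exp(np.random.default_rng(1).normal(6.5, 0.1, 50))
    rep = filter_recognition_trials(recog_table(list(fast) + list(normal)))
    assert rep.n_rt_floor_excluded == 30
    # SD stage must act on the log RTs of the surviving trials only
    lv = np.log(normal)
    oracle = int((np.abs(lv - lv.mean()) > 3 * lv.std()).sum())
    assert rep.n_sd_excluded == oracle


def test_refilter_monotone():
    rng = np.random.default_rng(2)
    df = recog_table(list(np.exp(rng.normal(6.5, 0.4, 300))))
    rep1 = filter_recognition_trials(df)
    rep2 = filter_recognition_trials(rep1.retained)
    assert rep2.n_rt_floor_excluded + rep2.n_sd_excluded <= \
        rep1.n_rt_floor_excluded + rep1.n_sd_excluded


def test_all_excluded_raises():
    with pytest.raises(ValueError):
        filter_recognition_trials(recog_table([50.0, 60.0]))


def test_filter_report_accounting():
    rng = np.random.default_rng(3)
    df = recog_table([90.0] + list(np.exp(rng.normal(6.5, 0.3, 200))))
    rep = filter_recognition_trials(df)
    assert rep.n_input == rep.n_retained + rep.n_rt_floor_excluded + rep.n_sd_excluded
    assert len(rep.flagged) == len(df)
    assert 0.0 <= rep.prop_sd_excluded <= 1.0


def test_probe_rt_window():
    df = make_trials(participant=[1] * 4, item_type=["R"] * 4,
                     phase="study", probe_present=[True] * 4,
                     probe_rt_ms=[99.0, 100.0, 2000.0, 2001.0])
    rep = filter_probe_rts(df)
    kept = sorted(rep.retained["probe_rt_ms"])
    assert kept == [100.0, 2000.0]       # both boundaries inclusive
    assert rep.n_rt_floor_excluded == 2


def test_probe_rt_all_in_range():
    df = make_trials(participant=[1] * 3, item_type=["F"] * 3, phase="study",
                     probe_present=[True] * 3, probe_rt_ms=[300.0, 450.0, 600.0])
    assert filter_probe_rts(df).n_rt_floor_excluded == 0


def test_conditionalize_on_old():
    df = make_trials(participant=[1] * 15,
                     item_type=["R"] * 10 + ["F"] * 5,
                     signed_error=list(np.linspace(-20, 20, 15)),
                     recognition_response=["old"] * 10 + ["new"] * 5)
    out = conditionalize_color_trials(df, on={"old"})
    assert len(out) == 10


def test_conditionalize_excludes_foils_even_if_old():
    df = make_trials(participant=[1] * 4, item_type=["foil"] * 2 + ["R"] * 2,
                     signed_error=[np.nan, np.nan, 5.0, -5.0],
                     recognition_response=["old"] * 4)
    out = conditionalize_color_trials(df, on={"old"})
    assert (out["item_type"] == "R").all() and len(out) == 2


def test_conditionalize_empty_warns():
    df = make_trials(participant=[1, 1], item_type=["R", "F"],
                     signed_error=[1.0, 2.0],
                     recognition_response=["new", "new"])
    with pytest.warns(RuntimeWarning):
        out = conditionalize_color_trials(df, on={"old"})
    assert len(out) == 0


def test_independent_know_subset():
    df = make_trials(
        participant=[1] * 20, item_type=["R"] * 20,
        recognition_response=["remember"] * 10 + ["know"] * 5 + ["no"] * 5)
    out = independent_know_subset(df)
    assert len(out) == 10
    assert (out["recognition_response"] == "know").mean() == pytest.approx(0.5)
    # no remember responses: identity
    no_rem = df[df.recognition_response != "remember"]
    assert independent_know_subset(no_rem).equals(no_rem)
    with pytest.warns(RuntimeWarning):
        independent_know_subset(df[df.recognition_response == "remember"])


def test_know_subset_commutes_with_participant_partition():
    rng = np.random.default_rng(4)
    df = make_trials(
        participant=list(rng.integers(1, 5, 60)), item_type=["R"] * 60,
        signed_error=list(rng.uniform(-180, 180, 60)),
        recognition_response=list(rng.choice(["remember", "know", "no"], 60)))
    whole = conditionalize_color_trials(independent_know_subset(df), on={"know"})
    parts = [conditionalize_color_trials(independent_know_subset(g), on={"know"})
             for _, g in df.groupby("participant")]
    concat = pd.concat(parts).sort_index()
    pd.testing.assert_frame_equal(whole.sort_index(), concat)
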