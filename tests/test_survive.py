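"""Exposure construction, dropout spells, and the Weibull PH likelihood."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from supportdyn.corpus import Message, Thread
from supportdyn.exceptions import DomainError, SchemaError
from supportdyn.simulate import (
    SimConfig,
    SurvivalTruth,
    simulate_survival_community,
    weibull_truth_spells,
)
from supportdyn.survive import (
    build_exposures,
    build_spells,
    fit_weibull_ph,
    percent_change_from_hr,
    standardize_covariates,
    _weibull_ph_loglik,
)

UTC = timezone.utc
T0 = datetime(2020, 1, 6, tzinfo=UTC)


def _msg(mid, tid, author, hours, position):
    return Message(mid, tid, author, T0 + timedelta(hours=hours), "x .", position)


def _scores(mids, emo=4.0, info=3.0):
    return pd.DataFrame(
        {"provide_emotional": emo, "provide_informational": info},
        index=pd.Index(list(mids), name="message_id"),
    )


# --- exposures ---------------------------------------------------------------

def test_exposure_counts_same_week_thread_messages():
    """A single post in a thread with 4 other same-week messages yields
    post_count_exposure 5 (the user's own message included)."""
    msgs = [_msg("m0", "t1", "alice", 0, 0)]
    msgs += [_msg(f"m{i}", "t1", f"other{i}", 10 * i, i) for i in range(1, 5)]
    exposures = build_exposures([Thread("t1", msgs)],
                                _scores([m.message_id for m in msgs]),
                                profiles={"alice": 1})
    assert len(exposures) == 1
    rec = exposures.iloc[0]
    assert rec["post_count_exposure"] == 5
    assert rec["week_index"] == 0
    assert rec["pct_thread_starters"] == 100.0
    assert rec["emo_exposure"] == pytest.approx(4.0)


def test_exposure_unions_threads_posted_same_week():
    t1 = [_msg("a0", "t1", "alice", 0, 0), _msg("a1", "t1", "x", 5, 1)]
    t2 = [_msg("b0", "t2", "y", 1, 0), _msg("b1", "t2", "alice", 6, 1),
          _msg("b2", "t2", "z", 30, 2)]
    exposures = build_exposures(
        [Thread("t1", t1), Thread("t2", t2)],
        _scores(["a0", "a1", "b0", "b1", "b2"]),
        profiles={"alice": 0},
    )
    assert exposures.iloc[0]["post_count_exposure"] == 5
    assert exposures.iloc[0]["pct_thread_starters"] == 50.0


def test_exposure_excludes_messages_outside_the_week():
    msgs = [_msg("m0", "t1", "alice", 0, 0),
            _msg("m1", "t1", "bob", 24 * 6, 1),     # within 7 days
            _msg("m2", "t1", "carol", 24 * 8, 2)]   # outside
    exposures = build_exposures([Thread("t1", msgs)], _scores(["m0", "m1", "m2"]),
                                profiles={"alice": 1})
    assert exposures.iloc[0]["post_count_exposure"] == 2


def test_exposure_requires_scores_for_exposed_messages():
    msgs = [_msg("m0", "t1", "alice", 0, 0), _msg("m1", "t1", "bob", 2, 1)]
    with pytest.raises(SchemaError, match="m1"):
        build_exposures([Thread("t1", msgs)], _scores(["m0"]), profiles={"alice": 1})


def test_exposures_match_hand_computed_schedule():
    """Scripted posting schedule: exposures equal the hand-computed table."""
    rows = []
    # alice posts weeks 0 and 2; her week-0 thread draws two replies,
    # one inside and one outside her 7-day window
    msgs = [
        _msg("a0", "t1", "alice", 0, 0),
        _msg("r1", "t1", "bob", 24 * 2, 1),
        _msg("r2", "t1", "bob", 24 * 9, 2),
        _msg("a1", "t2", "alice", 24 * 14, 0),
    ]
    threads = [Thread("t1", msgs[:3]), Thread("t2", msgs[3:])]
    scores = _scores(["a0", "r1", "r2", "a1"], emo=2.0, info=6.0)
    scores.loc["r1", "provide_emotional"] = 6.0
    exposures = build_exposures(threads, scores, profiles={"alice": 1})
    expected = pd.DataFrame({
        "week_index": [0, 2],
        "post_count_exposure": [2.0, 1.0],
        "emo_exposure": [4.0, 2.0],
        "pct_thread_starters": [100.0, 100.0],
    })
    got = exposures[["week_index", "post_count_exposure", "emo_exposure",
                     "pct_thread_starters"]].reset_index(drop=True)
    pd.testing.assert_frame_equal(got.astype(float), expected.astype(float))


# --- spells ------------------------------------------------------------------

def _exposure_rows(weeks, first=T0, user="u1"):
    return pd.DataFrame([
        {"user_id": user, "week_index": w, "n_posts": 1,
         "post_count_exposure": 1.0, "emo_exposure": 4.0, "info_exposure": 3.0,
         "pct_thread_starters": 100.0, "has_profile": 1, "first_post": first}
        for w in weeks
    ])


def test_single_post_long_follow_up_is_a_dropout():
    sp = build_spells(_exposure_rows([0]), gap=12,
                      end_of_data=T0 + timedelta(weeks=20))
    assert len(sp) == 1
    assert sp.iloc[0]["event"] == 1
    assert (sp.iloc[0]["start"], sp.iloc[0]["stop"]) == (0.0, 1.0)


def test_single_post_near_end_of_data_is_censored():
    sp = build_spells(_exposure_rows([0]), gap=12,
                      end_of_data=T0 + timedelta(weeks=5))
    assert sp.iloc[0]["event"] == 0


def test_silence_longer_than_gap_splits_episodes():
    sp = build_spells(_exposure_rows([0, 1, 20]), gap=12,
                      end_of_data=T0 + timedelta(weeks=40))
    assert sorted(sp["episode"].unique()) == [0, 1]
    ep0 = sp[sp.episode == 0]
    assert list(ep0["start"]) == [0.0, 1.0]
    assert list(ep0["stop"]) == [1.0, 2.0]
    assert list(ep0["event"]) == [0, 1]
    ep1 = sp[sp.episode == 1]
    assert list(ep1["start"]) == [0.0]  # clock restarts on rejoin
    assert ep1.iloc[0]["event"] == 1


def test_short_silence_within_gap_carries_covariates_forward():
    rows = _exposure_rows([0, 5])
    rows.loc[0, "emo_exposure"] = 6.0
    sp = build_spells(rows, gap=12, end_of_data=T0 + timedelta(weeks=40))
    assert len(sp) == 2
    first = sp.iloc[0]
    assert (first["start"], first["stop"]) == (0.0, 5.0)
    assert first["emo_exposure"] == 6.0


# --- standardization ---------------------------------------------------------

def test_standardize_zscores_and_interactions():
    rng = np.random.default_rng(0)
    sp = pd.DataFrame({
        "post_count_exposure": rng.uniform(1, 10, 100),
        "emo_exposure": rng.uniform(1, 7, 100),
        "info_exposure": rng.uniform(1, 7, 100),
        "pct_thread_starters": rng.uniform(0, 100, 100),
        "has_profile": 1,
    })
    out = standardize_covariates(sp)
    for c in ("post_count_exposure", "emo_exposure", "info_exposure",
              "pct_thread_starters"):
        assert out[c].mean() == pytest.approx(0.0, abs=1e-10)
        assert out[c].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
    assert (out["has_profile"] == 1).all()
    np.testing.assert_allclose(
        out["post_count_x_emo"],
        out["post_count_exposure"] * out["emo_exposure"], atol=1e-12)


def test_standardize_rejects_constant_covariate():
    sp = pd.DataFrame({
        "post_count_exposure": [3.0] * 10, "emo_exposure": np.arange(10.0),
        "info_exposure": np.arange(10.0), "pct_thread_starters": np.arange(10.0),
        "has_profile": 0,
    })
    with pytest.raises(DomainError, match="post_count_exposure"):
        standardize_covariates(sp)


# --- Weibull PH fitting ------------------------------------------------------

def _sim_spells(seed, n_users, log_hr, shape):
    sv = SurvivalTruth(log_hr=log_hr, shape=shape)
    cfg = SimConfig(seed=seed, n_users=n_users, survival=sv)
    _, _, truth = simulate_survival_community(cfg, build_corpus=False)
    return weibull_truth_spells(truth)


_NULL_HR = {"has_profile": 0.0, "pct_starters": 0.0, "post_count": 0.0,
            "emo_support": 0.0, "info_support": 0.0,
            "post_x_emo": 0.0, "post_x_info": 0.0}
COVS = ["has_profile", "pct_starters", "post_count", "emo_support", "info_support"]


def test_null_model_confidence_intervals_cover_one():
    """With all log-hazard-ratios 0, the 95% Wald CI covers HR=1 for >=90%
    of covariate estimates across seeded replicates."""
    covered = total = 0
    for rep in range(20):
        spells = _sim_spells(300 + rep, 250, _NULL_HR, shape=1.0)
        fit = fit_weibull_ph(spells, covariates=COVS)
        for c in COVS:
            lo = fit.coef[c] - 1.96 * fit.se[c]
            hi = fit.coef[c] + 1.96 * fit.se[c]
            covered += int(lo <= 0.0 <= hi)
            total += 1
    assert covered / total >= 0.90


def test_exponential_shape_recovery():
    spells = _sim_spells(31, 2500, _NULL_HR, shape=1.0)
    assert spells["event"].sum() >= 2000
    fit = fit_weibull_ph(spells, covariates=COVS)
    assert fit.shape == pytest.approx(1.0, abs=0.1)


def test_planted_hazard_ratio_recovery():
    log_hr = dict(_NULL_HR)
    log_hr["post_count"] = float(np.log(0.5))
    log_hr["emo_support"] = float(np.log(1.5))
    spells = _sim_spells(32, 5000, log_hr, shape=0.8)
    fit = fit_weibull_ph(spells, covariates=COVS)
    assert fit.hazard_ratio["post_count"] == pytest.approx(0.5, rel=0.15)
    assert fit.hazard_ratio["emo_support"] == pytest.approx(1.5, rel=0.15)
    assert fit.shape == pytest.approx(0.8, abs=0.1)


def test_fixed_shape_matches_exponential_regression_oracle():
    """With shape fixed at 1 the fit equals a Poisson GLM with log-exposure
    offset, an independently implemented exponential-regression oracle."""
    sm = pytest.importorskip("statsmodels.api")
    spells = _sim_spells(33, 600, _NULL_HR | {"post_count": -0.3}, shape=1.0)
    fit = fit_weibull_ph(spells, covariates=COVS, shape=1.0)
    X = sm.add_constant(spells[COVS].to_numpy())
    glm = sm.GLM(
        spells["event"].to_numpy(), X, family=sm.families.Poisson(),
        offset=np.log(spells["stop"] - spells["start"]),
    ).fit()
    ours = np.array([fit.coef["_intercept"]] + [fit.coef[c] for c in COVS])
    np.testing.assert_allclose(ours, glm.params, atol=2e-4)


def test_episode_splitting_leaves_likelihood_unchanged():
    spells = _sim_spells(34, 100, _NULL_HR, shape=0.9)
    X = np.column_stack([np.ones(len(spells)), spells[COVS].to_numpy()])
    theta = np.concatenate([[np.log(0.9)], np.full(X.shape[1], -0.1)])
    args = (spells["start"].to_numpy(), spells["stop"].to_numpy(),
            spells["event"].to_numpy(), X)
    nll_split, _ = _weibull_ph_loglik(theta, *args)

    # merge each user's intervals into a single record (covariates constant)
    merged = spells.groupby("user_id").agg(
        start=("start", "min"), stop=("stop", "max"), event=("event", "max"),
        **{c: (c, "first") for c in COVS},
    ).reset_index()
    Xm = np.column_stack([np.ones(len(merged)), merged[COVS].to_numpy()])
    nll_merged, _ = _weibull_ph_loglik(
        theta, merged["start"].to_numpy(), merged["stop"].to_numpy(),
        merged["event"].to_numpy(), Xm)
    assert nll_split == pytest.approx(nll_merged, rel=1e-10)


def test_fit_requires_events_and_valid_intervals():
    spells = pd.DataFrame({
        "start": [0.0], "stop": [1.0], "event": [0], "x": [0.5]})
    with pytest.raises(DomainError, match="no events"):
        fit_weibull_ph(spells, covariates=["x"])
    bad = pd.DataFrame({"start": [1.0], "stop": [1.0], "event": [1], "x": [0.5]})
    with pytest.raises(DomainError):
        fit_weibull_ph(bad, covariates=["x"])


# --- hazard-ratio interpretation ---------------------------------------------

@pytest.mark.parametrize("hr,direction,pct", [
    (0.511, "stay", 49),
    (0.853, "stay", 15),
    (0.343, "stay", 66),
    (1.048, "leave", 5),
    (1.0, "stay", 0),
    (1.0, "leave", 0),
])
def test_percent_change_from_hazard_ratio(hr, direction, pct):
    assert percent_change_from_hr(hr, direction) == pct


def test_percent_change_rejects_nonpositive_hr():
    with pytest.raises(DomainError):
        percent_change_from_hr(0.0, "stay")
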