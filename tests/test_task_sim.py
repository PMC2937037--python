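"""Stimulus generation, catch rule, observer dispatch, and trial-log I/O."""

import numpy as np
import pandas as pd
import pytest

import coincatch as cc
from coincatch import batch
from coincatch.task import ConfigError


# ------------------------------------------------------------------- config

def test_schedule_must_cover_trial_one():
    with pytest.raises(ConfigError):
        cc.SessionConfig(protocol="exp1", n_trials=100, prior_sd_schedule=((5, 0.2),))


def test_schedule_starts_strictly_increasing():
    with pytest.raises(ConfigError):
        cc.SessionConfig(protocol="exp2", n_trials=100,
                         prior_sd_schedule=((1, 0.2), (1, 0.05)))


def test_unknown_config_keys_rejected():
    d = cc.SessionConfig.exp1().to_dict()
    d["bogus_key"] = 1
    with pytest.raises(ConfigError, match="bogus_key"):
        cc.SessionConfig.from_dict(d)


@pytest.mark.parametrize("fmt", ["json", "yaml"])
def test_config_file_round_trip(tmp_path, fmt):
    cfg = cc.SessionConfig.exp2(first_sd=0.05, seed=9)
    path = tmp_path / f"cfg.{fmt}"
    if fmt == "json":
        cfg.to_json(path)
    else:
        import yaml
        path.write_text(yaml.safe_dump(cfg.to_dict()))
    assert cc.SessionConfig.from_file(path) == cfg


# ---------------------------------------------------------------- generation

def test_sessions_are_bit_reproducible():
    cfg = cc.SessionConfig.exp3(seed=17)
    a, b = cc.generate_session(cfg), cc.generate_session(cfg)
    pd.testing.assert_frame_equal(a, b)


def test_exp1_target_spread_matches_config():
    cfg = cc.SessionConfig.exp1(prior_sd=0.2, seed=2)
    df = cc.generate_session(cfg)
    assert len(df) == 400
    # sample sd within 3 standard errors (SE ~ sd/sqrt(2n))
    se = 0.2 / np.sqrt(2 * 400)
    assert abs(df["target"].std(ddof=1) - 0.2) < 3 * se


def test_exp2_spread_switches_at_schedule():
    cfg = cc.SessionConfig.exp2(first_sd=0.2, seed=3)
    df = cc.generate_session(cfg)
    assert len(df) == 500
    first = df.iloc[:250]["target"] - df.iloc[:250]["prior_mean_true"]
    second = df.iloc[250:]["target"] - df.iloc[250:]["prior_mean_true"]
    assert abs(first.std(ddof=1) - 0.2) < 3 * 0.2 / np.sqrt(500)
    assert abs(second.std(ddof=1) - 0.05) < 3 * 0.05 / np.sqrt(500)
    assert (df["prior_sd_true"].iloc[:250] == 0.2).all()
    assert (df["prior_sd_true"].iloc[250:] == 0.05).all()


def test_exp3_zero_hazard_never_switches():
    cfg = cc.SessionConfig.exp3(seed=4, switch_prob=0.0)
    df = cc.generate_session(cfg)
    assert df["prior_mean_true"].nunique() == 1
    assert (np.diff(df["trials_since_switch"]) == 1).all()


def test_exp3_mean_dwell_matches_closed_form():
    """Runs last >= refractory trials; afterwards each trial flips w.p. p,
    so run length = (refractory - 1) + Geometric(p), mean 9 + 1/0.2 = 14."""
    cfg = cc.SessionConfig.exp3(seed=0)
    stim = batch.batch_stimuli(cfg, 800, seed=0)
    runs = []
    for row in stim["trials_since_switch"]:
        resets = np.flatnonzero(row == 1)
        runs.extend(np.diff(resets))
    runs = np.asarray(runs)
    assert runs.min() >= cfg.refractory_trials
    expected = cfg.refractory_trials - 1 + 1 / cfg.switch_prob
    assert abs(runs.mean() - expected) < 3 * runs.std(ddof=1) / np.sqrt(len(runs))


def test_generative_calibration_of_cue_noise():
    cfg = cc.SessionConfig.exp1(prior_sd=0.05, seed=6, n_trials=2000)
    df = cc.generate_session(cfg)
    noise = df["cue"] - df["target"]
    assert abs(noise.std(ddof=1) - 0.1) < 3 * 0.1 / np.sqrt(2 * 2000)
    assert abs(noise.mean()) < 3 * 0.1 / np.sqrt(2000)


# --------------------------------------------------------------------- catch

@pytest.mark.parametrize("net, target, expected", [
    (0.1, 0.1, True),                  # dead centre
    (0.1, 0.1 + 0.03, False),          # a full coin width away
    (0.1, 0.1 + 0.015, True),          # half a width: boundary inclusive
])
def test_is_caught_distance_rule(net, target, expected):
    assert cc.is_caught(net, target, coin_width=0.03, overlap_fraction=0.5) is expected


# ----------------------------------------------------------------- observers

def test_oracle_regression_recovers_optimal_slope_and_intercept():
    cfg = cc.SessionConfig.exp1(prior_sd=0.2, seed=3)
    log = cc.run_observer(cc.generate_session(cfg), cc.ObserverSpec("oracle_fixed_prior"),
                          config=cfg)
    slope, intercept = np.polyfit(log["cue"], log["response"], 1)
    mu = log["prior_mean_true"].iloc[0]
    assert slope == pytest.approx(0.8, abs=1e-10)
    assert intercept == pytest.approx(0.2 * mu, abs=1e-10)


def test_flat_prior_observer_returns_cue():
    cfg = cc.SessionConfig.exp1(prior_sd=0.05, seed=3)
    log = cc.run_observer(cc.generate_session(cfg), cc.ObserverSpec("flat_prior_ml"),
                          config=cfg)
    np.testing.assert_array_equal(log["response"], log["cue"])


def test_oracle_with_motor_noise_slope_unbiased():
    """OLS slope over noisy oracle responses is unbiased (across sessions)."""
    slopes = []
    for i in range(100):
        cfg = cc.SessionConfig.exp1(prior_sd=0.2, seed=1000 + i, n_trials=100)
        log = cc.run_observer(cc.generate_session(cfg),
                              cc.ObserverSpec("oracle_fixed_prior", motor_noise_sd=0.02),
                              seed=i, config=cfg)
        slopes.append(np.polyfit(log["cue"], log["response"], 1)[0])
    slopes = np.asarray(slopes)
    assert abs(slopes.mean() - 0.8) < 3 * slopes.std(ddof=1) / 10


def test_oracle_catches_more_than_flat_prior_when_prior_is_narrow():
    caught = {}
    for model in ("oracle_fixed_prior", "flat_prior_ml"):
        rates = []
        for i in range(20):
            cfg = cc.SessionConfig.exp1(prior_sd=0.05, seed=200 + i)
            log = cc.run_observer(cc.generate_session(cfg), cc.ObserverSpec(model),
                                  config=cfg)
            rates.append(log["caught"].mean())
        caught[model] = np.mean(rates)
    assert caught["oracle_fixed_prior"] > caught["flat_prior_ml"]


def test_unknown_observer_model_rejected():
    cfg = cc.SessionConfig.exp1(seed=1)
    with pytest.raises(ValueError, match="unknown observer"):
        cc.run_observer(cc.generate_session(cfg), cc.ObserverSpec("nonsense"), config=cfg)


# ----------------------------------------------------------------------- I/O

def test_trial_log_csv_round_trip(tmp_path):
    cfg = cc.SessionConfig.exp3(seed=8)
    log = cc.run_observer(cc.generate_session(cfg), cc.ObserverSpec("switching"),
                          config=cfg)
    path = tmp_path / "trials.csv"
    cc.write_trial_log(log, path)
    back = cc.read_trial_log(path)
    assert list(back.columns) == cc.task.TRIAL_COLUMNS
    np.testing.assert_allclose(back["response"], log["response"], rtol=1e-8)
    np.testing.assert_allclose(back["cue"], log["cue"], rtol=1e-8)


def test_trial_log_missing_columns_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"cue": [0.1], "response": [0.2]}).to_csv(path, index=False)
    with pytest.raises(ValueError, match="missing columns"):
        cc.read_trial_log(path)


# ------------------------------------------------------ batch/scalar agreement

def test_batch_stimuli_statistics_match_config():
    cfg = cc.SessionConfig.exp1(prior_sd=0.05, seed=0)
    stim = batch.batch_stimuli(cfg, 200, seed=3)
    centered = stim["target"] - stim["prior_mean"]
    assert abs(centered.std(ddof=1) - 0.05) < 3 * 0.05 / np.sqrt(2 * centered.size)
    assert abs(stim["prior_mean"][:, 0].std(ddof=1) - 0.1) < 3 * 0.1 / np.sqrt(2 * 200)
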