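"""Binned least-squares read-out, switch alignment, prior reconstruction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coincatch as cc
from coincatch.analysis import bin_series, fit_bin, steady_state_gain


def _oracle_log(r, mu_p, n=40, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cue = rng.normal(mu_p, 0.2, n)
    resp = (1 - r) * mu_p + r * cue + noise * rng.standard_normal(n)
    return pd.DataFrame({"cue": cue, "response": resp,
                         "prior_mean_true": mu_p, "prior_sd_true": 0.2,
                         "trials_since_switch": np.nan,
                         "target": np.nan, "caught": np.nan,
                         "trial_index": np.arange(1, n + 1)})


def test_fit_bin_recovers_exact_linear_data():
    log = _oracle_log(0.8, 0.1, n=10)
    fit = fit_bin(log["cue"], log["response"])
    assert fit.r == pytest.approx(0.8, abs=1e-10)
    assert fit.mu_p == pytest.approx(0.1, abs=1e-10)
    assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)
    assert not fit.degenerate


def test_fit_bin_flags_flat_prior_when_response_is_cue():
    log = _oracle_log(1.0, 0.0, n=10)
    fit = fit_bin(log["cue"], log["cue"])
    assert fit.r == pytest.approx(1.0)
    assert fit.degenerate and np.isnan(fit.mu_p)


def test_fit_bin_singular_design_and_min_trials():
    with pytest.raises(ValueError, match="singular"):
        fit_bin([0.1] * 10, np.arange(10) / 10)
    with pytest.raises(ValueError, match="at least 3"):
        fit_bin([0.1, 0.2], [0.1, 0.2])


def test_ols_sampling_distribution_unbiased():
    """Across many noisy 10-trial bins, the mean fitted r and mu_p are within
    the tolerances expected of OLS."""
    rs, mus = [], []
    for i in range(500):
        log = _oracle_log(0.8, 0.05, n=10, noise=0.02, seed=i)
        fit = fit_bin(log["cue"], log["response"])
        rs.append(fit.r)
        if not fit.degenerate:
            mus.append(fit.mu_p)
    assert abs(np.mean(rs) - 0.8) < 0.05
    assert abs(np.mean(mus) - 0.05) < 0.02


def test_bin_series_counts_and_truncation():
    log = _oracle_log(0.5, 0.0, n=400, noise=0.01)
    assert len(bin_series(log)) == 40
    log405 = _oracle_log(0.5, 0.0, n=405, noise=0.01)
    with pytest.warns(UserWarning, match="dropping trailing"):
        binned = bin_series(log405)
    assert len(binned) == 40


def test_bin_series_emits_mu_error_against_truth():
    log = _oracle_log(0.6, 0.07, n=100, noise=0.0)
    binned = bin_series(log)
    np.testing.assert_allclose(binned["mu_p_error"], 0.0, atol=1e-9)


def test_nig_learner_converges_within_twenty_bins_on_narrow_prior():
    """Late-session binned gains from the NIG learner sit near the 0.2
    optimum of the narrow-prior protocol."""
    finals = []
    for i in range(10):
        cfg = cc.SessionConfig.exp1(prior_sd=0.05, seed=900 + i)
        log = cc.run_observer(cc.generate_session(cfg),
                              cc.ObserverSpec("nig_learner"), config=cfg)
        binned = bin_series(log)
        finals.append(binned["r"].iloc[-5:].mean())
    assert abs(np.mean(finals) - 0.2) < 0.1


@given(shift=st.floats(-0.3, 0.3), scale=st.floats(0.2, 3.0))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_bin_estimates_shift_and_scale_equivariance(shift, scale):
    log = _oracle_log(0.7, 0.04, n=10, noise=0.01, seed=3)
    base = fit_bin(log["cue"], log["response"])
    shifted = fit_bin(log["cue"] + shift, log["response"] + shift)
    scaled = fit_bin(log["cue"] * scale, log["response"] * scale)
    assert shifted.r == pytest.approx(base.r, abs=1e-9)
    assert shifted.mu_p == pytest.approx(base.mu_p + shift, abs=1e-7)
    assert scaled.r == pytest.approx(base.r, abs=1e-9)
    assert scaled.mu_p == pytest.approx(base.mu_p * scale, abs=1e-7)


# --------------------------------------------------------------- steady state

def test_steady_state_gain_on_oracle_log():
    cfg = cc.SessionConfig.exp1(prior_sd=0.2, seed=44)
    log = cc.run_observer(cc.generate_session(cfg),
                          cc.ObserverSpec("oracle_fixed_prior"), config=cfg)
    r, se = steady_state_gain(log, last_n=200)
    assert r == pytest.approx(0.8, abs=1e-9)
    assert se < 1e-9


def test_steady_state_gain_last_n_exceeding_log_is_error():
    log = _oracle_log(0.5, 0.0, n=100, noise=0.01)
    with pytest.raises(ValueError, match="last_n"):
        steady_state_gain(log, last_n=200)


def test_mean_switching_inflates_unremoved_gain():
    """On a switching-observer log the pooled slope without removing the true
    mean exceeds the mean-removed slope: the active mean adds positive
    covariance between cue and response."""
    rs_raw, rs_rm = [], []
    for i in range(10):
        cfg = cc.SessionConfig.exp3(seed=70 + i)
        log = cc.run_observer(cc.generate_session(cfg),
                              cc.ObserverSpec("switching"), config=cfg)
        rs_raw.append(steady_state_gain(log, remove_mean=False)[0])
        rs_rm.append(steady_state_gain(log, remove_mean=True)[0])
    assert np.mean(rs_raw) > np.mean(rs_rm)
    assert np.mean(rs_raw) > cc.compute_gain(0.1, 0.1)


# ------------------------------------------------------------ switch alignment

def test_align_to_switches_without_switches_returns_sentinel():
    log = _oracle_log(0.5, 0.0, n=100, noise=0.01)
    assert len(cc.align_to_switches(log)) == 0


def test_alignment_inversion_recovers_internal_mean_exactly():
    """With the true gain fixed, inverting the placement rule per trial on a
    noiseless switching-observer log returns the observer's own inferred
    mean estimate."""
    cfg = cc.SessionConfig.exp3(seed=91)
    stim = cc.generate_session(cfg)
    from coincatch.switching import SwitchModelConfig, run_switch_session
    sw = SwitchModelConfig.from_session_config(cfg)
    traj = run_switch_session(stim, sw)
    r = cc.compute_gain(sw.prior_sd, sw.likelihood_sd)
    implied = (traj["response"] - r * stim["cue"]) / (1 - r)
    np.testing.assert_allclose(implied, traj["inferred_mean"], atol=1e-10)


def test_switch_curve_crosses_midpoint_by_second_trial():
    curves = []
    for i in range(10):
        cfg = cc.SessionConfig.exp3(seed=300 + i)
        log = cc.run_observer(cc.generate_session(cfg),
                              cc.ObserverSpec("switching"), config=cfg)
        c = cc.align_to_switches(log, r_hat=0.5)
        if len(c):
            curves.append(c)
    agg = pd.concat(curves).groupby("k").apply(
        lambda g: np.average(g["aligned_estimate"], weights=g["n_switches"]),
        include_groups=False)
    assert agg.loc[1] < agg.loc[2]
    assert agg.loc[2] > 0.0        # crossed the inter-mean midpoint by k = 2


# ----------------------------------------------------------- prior trajectory

def test_prior_trajectory_reconstruction():
    binned = pd.DataFrame({"bin_index": [1, 2], "r": [0.8, 1.0],
                           "mu_p": [0.0, np.nan], "degenerate": [False, True]})
    priors = cc.prior_trajectory(binned, likelihood_sd=0.1)
    assert priors[0].sd == pytest.approx(0.2)
    assert priors[0].mean == 0.0
    assert priors[1].flat


def test_prior_round_trip_through_oracle_observer():
    """Oracle logs analysed end-to-end recover the generative prior spread."""
    sds = []
    for i in range(20):
        cfg = cc.SessionConfig.exp1(prior_sd=0.2, seed=600 + i)
        log = cc.run_observer(cc.generate_session(cfg),
                              cc.ObserverSpec("oracle_fixed_prior", motor_noise_sd=0.02),
                              seed=i, config=cfg)
        binned = bin_series(log)
        priors = cc.prior_trajectory(binned, likelihood_sd=0.1)
        sds.extend(p.sd for p in priors if not p.flat and np.isfinite(p.sd))
    assert np.median(sds) == pytest.approx(0.2, rel=0.15)
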