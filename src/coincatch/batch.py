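"""Vectorised many-session simulation.

Model fitting and the replication studies need hundreds of simulated
sessions per objective evaluation; these helpers run whole batches with
numpy arrays of shape ``(n_runs, n_trials)`` instead of looping the scalar
observers.  The scalar implementations in :mod:`coincatch.nig` and
:mod:`coincatch.linfilter` remain the reference; tests check the batch path
against them on identical stimuli to floating-point accuracy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nig import NIGState
from .task import SessionConfig

__all__ = [
    "batch_stimuli",
    "batch_nig",
    "batch_linear_filter",
    "batch_bin_ols",
    "bin_average",
    "curves_from_trajectories",
]


def batch_stimuli(config: SessionConfig, n_runs: int, seed: int) -> dict:
    """Generate ``n_runs`` independent sessions of ``config`` as arrays.

    Returns a dict of float arrays of shape ``(n_runs, n_trials)``:
    ``prior_mean``, ``prior_sd``, ``target``, ``cue`` (plus
    ``trials_since_switch`` for the two-state protocol).  Deterministic
    under ``seed``; the stream layout mirrors the scalar generator
    (independent substreams for means/switches, targets, and cues).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    mean_rng, target_rng, cue_rng = (np.random.default_rng(c) for c in ss)
    T = config.n_trials
    prior_sd = np.broadcast_to(config.prior_sd_per_trial(), (n_runs, T))
    out: dict = {}
    if config.prior_mean_mode == "random_subject_specific":
        mu = mean_rng.normal(0.0, config.subject_mean_sd, size=n_runs)
        prior_mean = np.repeat(mu[:, None], T, axis=1)
    else:
        means = np.asarray(config.two_state_means)
        idx = mean_rng.integers(2, size=n_runs)
        flips = mean_rng.random(size=(n_runs, T))
        prior_mean = np.empty((n_runs, T))
        dwell = np.empty((n_runs, T), dtype=int)
        tss = np.zeros(n_runs, dtype=int)
        for t in range(T):
            tss += 1
            prior_mean[:, t] = means[idx]
            dwell[:, t] = tss
            flip = (tss >= config.refractory_trials) & (flips[:, t] < config.switch_prob)
            idx = np.where(flip, 1 - idx, idx)
            tss = np.where(flip, 0, tss)
        out["trials_since_switch"] = dwell
    target = prior_mean + prior_sd * target_rng.standard_normal((n_runs, T))
    cue = target + config.likelihood_sd * cue_rng.standard_normal((n_runs, T))
    out.update(prior_mean=np.asarray(prior_mean), prior_sd=np.asarray(prior_sd),
               target=target, cue=cue)
    return out


def batch_nig(target: np.ndarray, cue: np.ndarray, init: NIGState,
              likelihood_sd: float, variance_mode: str = "mean") -> dict:
    """NIG respond-then-update recursion vectorised across runs.

    Returns per-trial trajectories (``mu``, ``var``, ``gain``, ``response``)
    of shape ``(n_runs, n_trials)``; ``lam``/``alpha`` are shared across runs
    (they depend only on trial count) and returned as 1-D arrays.
    """
    n_runs, T = target.shape
    mu = np.full(n_runs, float(init.mu))
    lam, alpha = float(init.lam), float(init.alpha)
    beta = np.full(n_runs, float(init.beta))
    l2 = likelihood_sd ** 2
    mu_out = np.empty((n_runs, T))
    var_out = np.empty((n_runs, T))
    resp = np.empty((n_runs, T))
    lam_out = np.empty(T)
    alpha_out = np.empty(T)
    for t in range(T):
        if variance_mode == "mean":
            var = beta / (alpha - 1.0)
        elif variance_mode == "mode":
            var = beta / (alpha + 1.0)
        elif variance_mode == "predictive":
            var = beta * (lam + 1.0) / (lam * (alpha - 1.0))
        else:
            raise ValueError(f"unknown variance mode {variance_mode!r}")
        gain = var / (var + l2)
        mu_out[:, t] = mu
        var_out[:, t] = var
        lam_out[t], alpha_out[t] = lam, alpha
        resp[:, t] = (1.0 - gain) * mu + gain * cue[:, t]
        x = target[:, t]
        beta = beta + lam * (x - mu) ** 2 / (2.0 * (lam + 1.0))
        mu = (lam * mu + x) / (lam + 1.0)
        lam += 1.0
        alpha += 0.5
    gain_out = var_out / (var_out + l2)
    return {"mu": mu_out, "var": var_out, "gain": gain_out, "response": resp,
            "lam": lam_out, "alpha": alpha_out}


def batch_linear_filter(target: np.ndarray, cue: np.ndarray, learning_rate: float,
                        var_init: float, likelihood_sd: float, window: int = 10,
                        mean_init: float = 0.0, mean_mode: str = "all") -> dict:
    """Linear-filter observer vectorised across runs (same semantics as
    :func:`coincatch.linfilter.run_lf_session`)."""
    n_runs, T = target.shape
    l2 = likelihood_sd ** 2
    var = np.full(n_runs, float(var_init))
    mean = np.full(n_runs, float(mean_init))
    csum = np.zeros(n_runs)
    var_out = np.empty((n_runs, T))
    mean_out = np.empty((n_runs, T))
    resp = np.empty((n_runs, T))
    for t in range(T):
        gain = var / (var + l2)
        var_out[:, t] = var
        mean_out[:, t] = mean
        resp[:, t] = (1.0 - gain) * mean + gain * cue[:, t]
        csum += target[:, t]
        if t + 1 >= window:
            obs = np.var(target[:, t + 1 - window:t + 1], axis=1, ddof=1)
            var = var + learning_rate * (obs - var)
        if mean_mode == "all":
            mean = csum / (t + 1.0)
        else:
            mean = target[:, max(0, t + 1 - window):t + 1].mean(axis=1)
    gain_out = var_out / (var_out + l2)
    return {"mean": mean_out, "var": var_out, "gain": gain_out, "response": resp}


def batch_bin_ols(cue: np.ndarray, response: np.ndarray, bin_size: int = 10,
                  degenerate_tol: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin OLS of response on cue, vectorised over (run, bin).

    Returns ``(r, mu_p)`` arrays of shape ``(n_runs, n_bins)``; ``mu_p`` is
    NaN where the slope is within ``degenerate_tol`` of 1 (flat-prior
    degenerate bins).  Trailing trials that do not fill a bin are dropped.
    """
    n_runs, T = cue.shape
    n_bins = T // bin_size
    c = cue[:, :n_bins * bin_size].reshape(n_runs, n_bins, bin_size)
    y = response[:, :n_bins * bin_size].reshape(n_runs, n_bins, bin_size)
    cm = c.mean(axis=2, keepdims=True)
    ym = y.mean(axis=2, keepdims=True)
    sxx = ((c - cm) ** 2).sum(axis=2)
    sxy = ((c - cm) * (y - ym)).sum(axis=2)
    r = sxy / sxx
    intercept = ym[:, :, 0] - r * cm[:, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = intercept / (1.0 - r)
    mu = np.where(np.abs(1.0 - r) < degenerate_tol, np.nan, mu)
    return r, mu


def bin_average(traj: np.ndarray, bin_size: int = 10) -> np.ndarray:
    """Mean of a per-trial trajectory within consecutive bins (trailing
    partial bin dropped); shape ``(n_runs, n_bins)``."""
    n_runs, T = traj.shape
    n_bins = T // bin_size
    return traj[:, :n_bins * bin_size].reshape(n_runs, n_bins, bin_size).mean(axis=2)


def curves_from_trajectories(mu_err: np.ndarray, gain: np.ndarray,
                             bin_size: int = 10) -> pd.DataFrame:
    """Across-run average learning curves from per-trial trajectories.

    Bins the internal prior-mean error and gain into 10-trial bins, then
    averages across runs; standard errors are across-run SEs of the per-run
    bin means.
    """
    me = bin_average(mu_err, bin_size)
    g = bin_average(gain, bin_size)
    n_runs = me.shape[0]
    sqrt_n = np.sqrt(n_runs)
    return pd.DataFrame({
        "bin_index": np.arange(1, me.shape[1] + 1),
        "mu_err": me.mean(axis=0),
        "gain": g.mean(axis=0),
        "se_mu_err": me.std(axis=0, ddof=1) / sqrt_n if n_runs > 1 else np.nan,
        "se_gain": g.std(axis=0, ddof=1) / sqrt_n if n_runs > 1 else np.nan,
    })
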