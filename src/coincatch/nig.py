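"""Conjugate Normal-scaled-Inverse-Gamma (NIG) learner for protocols 1-2.

The observer maintains a joint belief over the prior's unknown mean and
variance, ``(mu_p, sigma_p^2) ~ NIG(mu, lam, alpha, beta)``:

    sigma_p^2 ~ InvGamma(alpha, beta)
    mu_p | sigma_p^2 ~ N(mu, sigma_p^2 / lam)

The NIG family is conjugate for Gaussian observations, so each revealed
target position updates the four hyperparameters in closed form.  The
observer's four *initial* hyperparameters are the model's free parameters;
its growing certainty (``lam`` and ``alpha`` increase by 1 and 1/2 per
trial) is the mechanism behind the slowing learning rate late in a session.

Each trial the observer responds *before* updating: it plugs its current
point estimates (posterior mean of mu_p, posterior mean of sigma_p^2) into
the linear placement rule, then updates on the revealed target.  Given the
target, the cue carries no extra information about the prior, so only the
target enters the update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaussian import compute_gain, optimal_estimate

__all__ = [
    "NIGState",
    "nig_update",
    "nig_point_estimates",
    "nig_gain",
    "run_nig_session",
    "average_model_curves",
]


@dataclass(frozen=True)
class NIGState:
    """Hyperparameters of the NIG belief over the prior's mean and variance.

    ``lam`` acts as an effective observation count for the mean, ``alpha``
    and ``beta`` shape the Inverse-Gamma marginal over the variance; the
    posterior mean of the variance, ``beta / (alpha - 1)``, exists only for
    ``alpha > 1``.
    """

    mu: float
    lam: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"lam, alpha, beta must all be > 0, got ({self.lam}, {self.alpha}, {self.beta})"
            )


def nig_update(state: NIGState, observation: float) -> NIGState:
    """One conjugate update on a revealed target position.

    mu'    = (lam mu + x) / (lam + 1)
    lam'   = lam + 1
    alpha' = alpha + 1/2
    beta'  = beta + lam (x - mu)^2 / (2 (lam + 1))
    """
    if not np.isfinite(observation):
        raise ValueError(f"observation must be finite, got {observation}")
    x = float(observation)
    lam = state.lam
    return NIGState(
        mu=(lam * state.mu + x) / (lam + 1.0),
        lam=lam + 1.0,
        alpha=state.alpha + 0.5,
        beta=state.beta + lam * (x - state.mu) ** 2 / (2.0 * (lam + 1.0)),
    )


def nig_point_estimates(state: NIGState) -> tuple[float, float]:
    """Posterior point estimates ``(E[mu_p], E[sigma_p^2]) = (mu, beta/(alpha-1))``.

    Raises for ``alpha <= 1`` where the posterior mean of the variance is
    undefined.
    """
    if not state.alpha > 1.0:
        raise ValueError(f"variance estimate undefined for alpha <= 1 (alpha={state.alpha})")
    return state.mu, state.beta / (state.alpha - 1.0)


def _variance_estimate(state: NIGState, mode: str) -> float:
    if mode == "mean":
        return nig_point_estimates(state)[1]
    if mode == "mode":
        return state.beta / (state.alpha + 1.0)
    if mode == "predictive":
        # Variance of the Student-t posterior predictive of the next target.
        if not state.alpha > 1.0:
            raise ValueError("predictive variance undefined for alpha <= 1")
        return state.beta * (state.lam + 1.0) / (state.lam * (state.alpha - 1.0))
    raise ValueError(f"unknown variance mode {mode!r}")


def nig_gain(state: NIGState, likelihood_sd: float, variance_mode: str = "mean") -> float:
    """Cue weight implied by the current belief: gain of sqrt(E[sigma_p^2])."""
    var = _variance_estimate(state, variance_mode)
    return compute_gain(np.sqrt(var), likelihood_sd)


def run_nig_session(
    stimuli: pd.DataFrame,
    init: NIGState,
    likelihood_sd: float | None = None,
    variance_mode: str = "mean",
) -> pd.DataFrame:
    """Run the NIG observer through a stimulus stream.

    Returns a trajectory DataFrame (one row per trial) with the belief state
    before the trial's update, the derived variance estimate and gain, and
    the response.  ``likelihood_sd`` defaults to the value recorded in the
    session config attached to ``stimuli``.
    """
    if likelihood_sd is None:
        likelihood_sd = stimuli.attrs.get("config", {}).get("likelihood_sd", 0.1)
    cues = stimuli["cue"].to_numpy()
    targets = stimuli["target"].to_numpy()
    n = len(cues)
    rows = np.empty((n, 7))
    state = init
    for t in range(n):
        var = _variance_estimate(state, variance_mode)
        gain = compute_gain(np.sqrt(var), likelihood_sd)
        response = optimal_estimate(state.mu, cues[t], gain)
        rows[t] = (state.mu, state.lam, state.alpha, state.beta, var, gain, response)
        state = nig_update(state, targets[t])
    out = pd.DataFrame(rows, columns=["mu", "lam", "alpha", "beta", "var_estimate", "gain", "response"])
    out.insert(0, "trial_index", np.arange(1, n + 1))
    return out


def average_model_curves(
    config,
    init: NIGState,
    n_runs: int,
    seed: int,
    bin_size: int = 10,
    variance_mode: str = "mean",
) -> pd.DataFrame:
    """Bin-wise average model curves over many simulated sessions.

    Runs ``n_runs`` independent sessions of ``config`` (vectorised across
    runs), and averages the observer's internal prior-mean error
    ``mu - prior_mean_true`` and gain within each 10-trial bin and across
    runs.  Deterministic under ``seed``.  Returns a DataFrame with columns
    ``bin_index, mu_err, gain`` plus across-run standard errors.
    """
    from . import batch

    stim = batch.batch_stimuli(config, n_runs, seed)
    traj = batch.batch_nig(stim["target"], stim["cue"], init,
                           config.likelihood_sd, variance_mode=variance_mode)
    mu_err = traj["mu"] - stim["prior_mean"]
    return batch.curves_from_trajectories(mu_err, traj["gain"], bin_size)
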