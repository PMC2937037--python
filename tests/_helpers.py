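"""Independent oracles and small utilities shared by the test suite.

These deliberately avoid the code paths they check: the grid posterior
integrates Bayes' rule numerically on a (mu, sigma^2) lattice, and the
enumeration oracle sums over all admissible mean sequences of the switching
process.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def grid_posterior_moments(init, observations, mu_range, var_range, n_grid=400):
    """Posterior means of (mu, sigma^2) by dense lattice integration.

    Prior: sigma^2 ~ InvGamma(alpha, beta); mu | sigma^2 ~ N(mu0, sigma^2/lam).
    Likelihood: each observation ~ N(mu, sigma^2).
    """
    mu_grid = np.linspace(*mu_range, n_grid)
    v_grid = np.linspace(*var_range, n_grid)
    M, V = np.meshgrid(mu_grid, v_grid, indexing="ij")
    logp = (stats.invgamma.logpdf(V, init.alpha, scale=init.beta)
            + stats.norm.logpdf(M, init.mu, np.sqrt(V / init.lam)))
    for x in observations:
        logp += stats.norm.logpdf(x, M, np.sqrt(V))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return float((p * M).sum()), float((p * V).sum())


def _norm_lpdf(x, m, s):
    return -0.5 * ((x - m) / s) ** 2 - np.log(s) - 0.5 * np.log(2 * np.pi)


def enumerate_switch_posterior(targets, cues, config):
    """Cue-conditioned posterior over the active mean at every trial, by
    exhaustive enumeration over admissible mean sequences.

    The generative process starts uniformly over the two means with dwell 1;
    after a trial at dwell d >= refractory the mean flips with probability
    switch_prob.  Returns an array of shape (T, 2):
    P(mean_t | targets_1..t-1, cue_t).
    """
    p, R = config.switch_prob, config.refractory_trials
    means = np.asarray(config.means)
    T = len(targets)
    sd_cue = np.sqrt(config.prior_sd ** 2 + config.likelihood_sd ** 2)

    def prefixes(tlen):
        out = []

        def rec(seq, dwell, logw):
            if len(seq) == tlen:
                out.append((logw, seq))
                return
            if not seq:
                for m0 in (0, 1):
                    rec([m0], 1, logw + np.log(0.5))
                return
            m, d = seq[-1], dwell
            if d >= R:
                rec(seq + [1 - m], 1, logw + np.log(p))
                rec(seq + [m], d + 1, logw + np.log(1 - p))
            else:
                rec(seq + [m], d + 1, logw)

        rec([], 0, 0.0)
        return out

    post = np.zeros((T, 2))
    for t in range(T):
        acc = np.zeros(2)
        for logw, seq in prefixes(t + 1):
            lw = logw + sum(_norm_lpdf(targets[i], means[seq[i]], config.prior_sd)
                            for i in range(t))
            lw += _norm_lpdf(cues[t], means[seq[t]], sd_cue)
            acc[seq[t]] += np.exp(lw)
        post[t] = acc / acc.sum()
    return post


def bins_to_criterion(r_bins, target, tol=0.1):
    """First bin (1-based) where |r - target| < tol; censored at n_bins + 1."""
    r_bins = np.atleast_2d(r_bins)
    ok = np.abs(r_bins - target) < tol
    idx = np.argmax(ok, axis=-1)
    never = ~ok.any(axis=-1)
    return np.where(never, r_bins.shape[-1] + 1, idx + 1)


def bins_to_midpoint(gain_bins, start_gain, target_gain):
    """First bin where the binned gain crosses halfway from its starting
    value toward the new true gain; censored at n_bins + 1.

    ``start_gain`` may be a per-run array (each run measured from its own
    starting point), which makes the statistic invariant to how far the
    segment starts from the target — a scale-free adaptation-speed measure.
    """
    gain_bins = np.atleast_2d(gain_bins)
    start = np.broadcast_to(np.asarray(start_gain, dtype=float),
                            gain_bins.shape[:-1])
    half = 0.5 * (start + target_gain)
    up = target_gain > start
    ok = np.where(up[..., None], gain_bins >= half[..., None],
                  gain_bins <= half[..., None])
    idx = np.argmax(ok, axis=-1)
    never = ~ok.any(axis=-1)
    return np.where(never, gain_bins.shape[-1] + 1, idx + 1)
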