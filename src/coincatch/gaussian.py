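"""Closed-form Gaussian cue-integration primitives.

In the coin-catching task the target coin is drawn from a Gaussian prior
``N(mu_p, sigma_p^2)`` and the visible cue coin from a Gaussian likelihood
``N(target, sigma_l^2)``.  Under squared-error loss the optimal net placement
is the posterior mean, a fixed linear blend of the prior mean and the cue:

    mu_t = (1 - r) * mu_p + r * mu_l,      r = sigma_p^2 / (sigma_p^2 + sigma_l^2)

``r`` is an alternate form of the Kalman gain: it is 0 for a delta prior
(ignore the cue) and 1 for a flat prior (maximum-likelihood behaviour,
respond at the cue).  Everything else in the package — the simulated
observers, the binned least-squares read-out, the reconstructed priors —
is built from these three functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaussianSpec",
    "FLAT_PRIOR",
    "compute_gain",
    "optimal_estimate",
    "reconstruct_prior",
]


@dataclass(frozen=True)
class GaussianSpec:
    """A 1-D Gaussian over screen positions (screen spans [-0.5, 0.5]).

    ``sd = 0`` is permitted as a degenerate delta (used in limit checks);
    ``flat=True`` marks the infinite-spread sentinel returned when a fitted
    gain reaches 1 and the prior is unidentifiable (the "flat prior" regime).
    """

    mean: float
    sd: float
    flat: bool = False

    def __post_init__(self) -> None:
        if not self.flat and not self.sd >= 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


#: Sentinel for an infinitely broad (uninformative) prior.
FLAT_PRIOR = GaussianSpec(mean=math.nan, sd=math.inf, flat=True)


def compute_gain(prior_sd, likelihood_sd):
    """Kalman-style cue weight r = sigma_p^2 / (sigma_p^2 + sigma_l^2).

    Monotone increasing in ``prior_sd`` and decreasing in ``likelihood_sd``.
    Accepts scalars or arrays (broadcast).  Both spreads zero is a 0/0
    domain error.
    """
    p2 = np.square(np.asarray(prior_sd, dtype=float))
    l2 = np.square(np.asarray(likelihood_sd, dtype=float))
    denom = p2 + l2
    if np.any(denom == 0):
        raise ValueError("prior_sd and likelihood_sd cannot both be zero (0/0 gain)")
    out = p2 / denom
    if out.ndim == 0:
        return float(out)
    return out


def optimal_estimate(prior_mean, cue, gain):
    """Posterior-mean placement ``(1 - gain) * prior_mean + gain * cue``.

    For ``gain`` in [0, 1] the result lies between the prior mean and the cue.
    """
    prior_mean = np.asarray(prior_mean, dtype=float)
    cue = np.asarray(cue, dtype=float)
    gain = np.asarray(gain, dtype=float)
    out = (1.0 - gain) * prior_mean + gain * cue
    if out.ndim == 0:
        return float(out)
    return out


def reconstruct_prior(gain: float, prior_mean: float, likelihood_sd: float) -> GaussianSpec:
    """Invert the gain formula to recover the prior implied by a fitted gain.

    With the likelihood spread known, ``sigma_p = sigma_l * sqrt(r / (1 - r))``.
    A gain at or above 1 corresponds to an unbounded prior spread and returns a
    flat-prior sentinel (infinite sd, ``flat=True``) rather than raising: gains
    near 1 are the empirically observed early-session "flat prior" regime.
    Round-trips with :func:`compute_gain` for gains in [0, 1).
    """
    if likelihood_sd <= 0:
        raise ValueError("likelihood_sd must be > 0")
    if gain >= 1.0:
        return GaussianSpec(mean=prior_mean, sd=math.inf, flat=True)
    if gain < 0:
        raise ValueError(f"gain must be >= 0, got {gain}")
    sd = likelihood_sd * math.sqrt(gain / (1.0 - gain))
    return GaussianSpec(mean=prior_mean, sd=sd)
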