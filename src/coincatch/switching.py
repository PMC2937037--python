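"""Change-point ideal observer for protocol 3 (switching prior mean).

The observer knows the prior's spread, the two candidate means, and the
switching process (10-trial refractory period, then per-trial Bernoulli
hazard 0.2); it only has to infer which mean is currently active.  Because
the generative hazard depends on how long the current mean has been in
force, the exact posterior is a forward recursion over joint
(mean index, dwell time) states — a hidden semi-Markov filter.  A
constant-hazard approximation (ignore the refractory period) is available
behind a flag for comparison.

Per trial the observer:

1. places the net by conditioning the current belief on the cue and taking
   the posterior-mean placement under the resulting two-component mixture
   (MAP placement available behind a flag);
2. updates the belief on the revealed target (given the target, the cue is
   conditionally independent of the active mean and is not double-counted);
3. propagates the belief one step through the switching dynamics.

Dwell time is capped at ``d_max`` (default 60), beyond which the hazard is
constant anyway, so the capped bin is exact, not an approximation, whenever
``d_max >= refractory_trials``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaussian import compute_gain, optimal_estimate

__all__ = [
    "SwitchModelConfig",
    "initial_belief",
    "propagate",
    "place_net",
    "observe_target",
    "run_switch_session",
]


@dataclass(frozen=True)
class SwitchModelConfig:
    means: tuple
    prior_sd: float
    likelihood_sd: float
    refractory_trials: int = 10
    switch_prob: float = 0.2
    d_max: int = 60
    constant_hazard: bool = False
    placement: str = "posterior_mean"   # or "map"

    def __post_init__(self) -> None:
        if not self.prior_sd > 0:
            raise ValueError("prior_sd must be > 0")
        if not self.likelihood_sd > 0:
            raise ValueError("likelihood_sd must be > 0")
        if len(self.means) != 2 or self.means[0] == self.means[1]:
            raise ValueError("means must be two distinct positions")
        if self.d_max < max(2, self.refractory_trials):
            raise ValueError("d_max must be >= refractory_trials (and >= 2)")
        object.__setattr__(self, "means", tuple(float(m) for m in self.means))

    @classmethod
    def from_session_config(cls, config, **kw) -> "SwitchModelConfig":
        """Build the (no-free-parameter) observer from the generative truth."""
        return cls(means=config.two_state_means,
                   prior_sd=config.prior_sd_schedule[0][1],
                   likelihood_sd=config.likelihood_sd,
                   refractory_trials=config.refractory_trials,
                   switch_prob=config.switch_prob, **kw)

    def hazard(self) -> np.ndarray:
        """Switch probability as a function of dwell time d = 1..d_max."""
        d = np.arange(1, self.d_max + 1)
        if self.constant_hazard:
            return np.full(self.d_max, self.switch_prob)
        return np.where(d >= self.refractory_trials, self.switch_prob, 0.0)


def initial_belief(config: SwitchModelConfig) -> np.ndarray:
    """Uniform over the two means, dwell time 1 (matches the generator's start)."""
    b = np.zeros((2, config.d_max))
    b[:, 0] = 0.5
    return b


def _normalize(belief: np.ndarray) -> np.ndarray:
    total = belief.sum()
    if not total > 0:
        raise ValueError("belief has no mass (all-zero likelihood?)")
    return belief / total


def propagate(belief: np.ndarray, config: SwitchModelConfig) -> np.ndarray:
    """One step of the switching dynamics over (mean, dwell) states.

    Mass at (m, d) stays in m moving to dwell d+1 with probability
    1 - h(d), and flips to (other mean, dwell 1) with probability h(d);
    dwell at the cap accumulates there.
    """
    h = config.hazard()
    stay = belief * (1.0 - h)
    out = np.zeros_like(belief)
    out[:, 1:] = stay[:, :-1]
    out[:, -1] += stay[:, -1]                       # cap bin accumulates
    flipped = (belief * h).sum(axis=1)
    out[0, 0] += flipped[1]
    out[1, 0] += flipped[0]
    return _normalize(out)


def place_net(belief: np.ndarray, cue: float, config: SwitchModelConfig) -> float:
    """Posterior-mean net placement given the cue (belief is not mutated).

    The cue's marginal likelihood under mean m integrates out the target:
    ``N(cue; mean_m, prior_sd^2 + likelihood_sd^2)``.  Each mean contributes
    its within-state optimal estimate with the known gain; the placement is
    their posterior-probability mixture (or the MAP component's estimate).
    """
    means = np.asarray(config.means)
    var = config.prior_sd ** 2 + config.likelihood_sd ** 2
    logw = -0.5 * (cue - means) ** 2 / var
    w = np.exp(logw - logw.max())
    p_mean = belief.sum(axis=1) * w
    p_mean = p_mean / p_mean.sum()
    r = compute_gain(config.prior_sd, config.likelihood_sd)
    estimates = optimal_estimate(means, cue, r)
    if config.placement == "map":
        return float(estimates[int(np.argmax(p_mean))])
    return float(p_mean @ estimates)


def cue_posterior(belief: np.ndarray, cue: float, config: SwitchModelConfig) -> np.ndarray:
    """P(active mean | history, cue) — the mixture weights used by place_net."""
    means = np.asarray(config.means)
    var = config.prior_sd ** 2 + config.likelihood_sd ** 2
    logw = -0.5 * (cue - means) ** 2 / var
    w = np.exp(logw - logw.max())
    p = belief.sum(axis=1) * w
    return p / p.sum()


def observe_target(belief: np.ndarray, target: float, config: SwitchModelConfig) -> np.ndarray:
    """Condition the belief on the revealed target, ``N(target; mean_m, prior_sd^2)``."""
    means = np.asarray(config.means)
    logw = -0.5 * (target - means) ** 2 / config.prior_sd ** 2
    w = np.exp(logw - logw.max())
    return _normalize(belief * w[:, None])


def run_switch_session(stimuli: pd.DataFrame, config: SwitchModelConfig) -> pd.DataFrame:
    """Respond / observe / propagate loop over a protocol-3 stimulus stream.

    Per trial the trajectory records the cue-conditioned probability of the
    first mean (``p_mean1``), the inferred mean estimate
    ``sum_m P(m | history, cue) * mean_m`` (what the response implies through
    the placement rule), and the response.
    """
    cues = stimuli["cue"].to_numpy()
    targets = stimuli["target"].to_numpy()
    means = np.asarray(config.means)
    n = len(cues)
    belief = initial_belief(config)
    rows = np.empty((n, 3))
    for t in range(n):
        p = cue_posterior(belief, cues[t], config)
        response = place_net(belief, cues[t], config)
        rows[t] = (p[0], float(p @ means), response)
        belief = observe_target(belief, targets[t], config)
        belief = propagate(belief, config)
    out = pd.DataFrame(rows, columns=["p_mean1", "inferred_mean", "response"])
    out.insert(0, "trial_index", np.arange(1, n + 1))
    return out
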