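"""Fixed-learning-rate linear-filter observer (the non-Bayesian comparison).

This observer only *estimates the prior's variance*: each trial it computes
the unbiased sample variance of the last ten observed targets and nudges its
running variance estimate toward it with a constant learning rate,

    var' = var + rate * (window_variance - var),

a first-order linear filter whose adaptation time constant (~1/rate trials)
never changes.  That constancy is the model's diagnostic failure mode: it
adapts equally fast early and late in a session, unlike the conjugate NIG
learner (and unlike human subjects).  Its two free parameters are the
learning rate and the initial variance.

The prior-mean estimate is not part of the model proper; by default it is
the running mean of all targets seen so far (switchable to the 10-trial
window mean), which keeps the model's failure specific to variance dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gaussian import compute_gain, optimal_estimate

__all__ = [
    "LinearFilterState",
    "window_variance",
    "lf_update",
    "run_lf_session",
]

#: Sentinel returned when the window holds fewer than two points.
NO_OBSERVATION = None


@dataclass(frozen=True)
class LinearFilterState:
    var_estimate: float
    mean_estimate: float
    window: tuple = ()
    learning_rate: float = 0.1
    var_init: float = 0.04
    window_size: int = 10
    mean_mode: str = "all"          # "all" running mean, or "window"
    n_seen: int = 0
    sum_seen: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.var_estimate < 0 or self.var_init < 0:
            raise ValueError("variance estimates must be >= 0")

    @classmethod
    def initial(cls, learning_rate: float, var_init: float, mean_init: float = 0.0,
                window_size: int = 10, mean_mode: str = "all") -> "LinearFilterState":
        return cls(var_estimate=var_init, mean_estimate=mean_init,
                   learning_rate=learning_rate, var_init=var_init,
                   window_size=window_size, mean_mode=mean_mode)


def window_variance(window):
    """Unbiased sample variance (divisor n-1) of the windowed targets.

    Returns the no-observation sentinel (``None``) for fewer than two points.
    """
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        return NO_OBSERVATION
    return float(np.var(w, ddof=1))


def lf_update(state: LinearFilterState, new_target: float) -> LinearFilterState:
    """Push a target into the window; update the variance once the window is full.

    Before the window holds ``window_size`` targets no variance observation
    is formed and ``var_estimate`` stays at its initial value.  The update
    preserves non-negativity (a convex combination of two non-negative terms).
    """
    window = (state.window + (float(new_target),))[-state.window_size:]
    n_seen = state.n_seen + 1
    sum_seen = state.sum_seen + float(new_target)
    var = state.var_estimate
    if len(window) >= state.window_size:
        obs = window_variance(window)
        var = var + state.learning_rate * (obs - var)
    mean = sum_seen / n_seen if state.mean_mode == "all" else float(np.mean(window))
    return replace(state, window=window, n_seen=n_seen, sum_seen=sum_seen,
                   var_estimate=var, mean_estimate=mean)


def run_lf_session(
    stimuli: pd.DataFrame,
    state_init: LinearFilterState,
    likelihood_sd: float | None = None,
) -> pd.DataFrame:
    """Respond-then-update loop over a stimulus stream.

    The response uses the pre-trial variance and mean estimates through the
    same linear placement rule as every other observer; the gain is
    ``compute_gain(sqrt(var_estimate), likelihood_sd)``.
    """
    if likelihood_sd is None:
        likelihood_sd = stimuli.attrs.get("config", {}).get("likelihood_sd", 0.1)
    cues = stimuli["cue"].to_numpy()
    targets = stimuli["target"].to_numpy()
    n = len(cues)
    rows = np.empty((n, 4))
    state = state_init
    for t in range(n):
        gain = compute_gain(np.sqrt(state.var_estimate), likelihood_sd)
        response = optimal_estimate(state.mean_estimate, cues[t], gain)
        rows[t] = (state.mean_estimate, state.var_estimate, gain, response)
        state = lf_update(state, targets[t])
    out = pd.DataFrame(rows, columns=["mean_estimate", "var_estimate", "gain", "response"])
    out.insert(0, "trial_index", np.arange(1, n + 1))
    return out
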