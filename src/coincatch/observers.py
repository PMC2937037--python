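"""Synthetic subjects: dispatch a parameterised observer over a session.

Observers stand in for human subjects so the whole measurement pipeline can
be exercised without behavioural data.  All observers see the cue before
responding and the target only afterwards, matching the trial order of the
task (cue coin displayed first, target revealed after the net is placed).

Available models:

``oracle_fixed_prior``
    Responds with the optimal estimate using the *true* generative prior of
    each trial — the Bayes-optimal benchmark (slope 0.8 / 0.2 in the wide /
    narrow conditions).
``flat_prior_ml``
    Maximum-likelihood behaviour: responds at the cue (gain 1).
``nig_learner``
    The conjugate NIG learner (:mod:`coincatch.nig`).
``linear_filter``
    The fixed-rate variance tracker (:mod:`coincatch.linfilter`).
``switching``
    The change-point ideal observer (:mod:`coincatch.switching`).

Motor noise (Gaussian jitter on the emitted response, default 0) is added
after the model's deliberate placement and does not feed back into any
observer's internal state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaussian import compute_gain, optimal_estimate
from .linfilter import LinearFilterState, run_lf_session
from .nig import NIGState, run_nig_session
from .switching import SwitchModelConfig, run_switch_session
from .task import SessionConfig, is_caught

__all__ = ["ObserverSpec", "run_observer", "OBSERVER_MODELS"]

OBSERVER_MODELS = ("oracle_fixed_prior", "flat_prior_ml", "nig_learner",
                   "linear_filter", "switching")

#: A broadly uncertain reference initialisation for the NIG learner:
#: weak mean belief at screen centre, initial variance estimate 0.1
#: (gain ~0.91, i.e. close to the flat-prior behaviour subjects start with).
DEFAULT_NIG_INIT = NIGState(mu=0.0, lam=1.0, alpha=1.2, beta=0.02)


@dataclass(frozen=True)
class ObserverSpec:
    """Which observer model to run, with model-specific parameters."""

    model: str
    model_params: dict = field(default_factory=dict)
    motor_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be >= 0")


def _config_from(stimuli: pd.DataFrame, config: SessionConfig | None) -> dict:
    if config is not None:
        return config.to_dict()
    return dict(stimuli.attrs.get("config", {}))


def run_observer(
    stimuli: pd.DataFrame,
    observer: ObserverSpec,
    seed: int = 0,
    config: SessionConfig | None = None,
) -> pd.DataFrame:
    """Run an observer over a stimulus stream; returns a completed trial log.

    The returned DataFrame is a copy of ``stimuli`` with ``response`` and
    ``caught`` filled in.  ``seed`` drives motor noise only, so the stimulus
    stream is untouched by observer choices.  The catch rule uses the coin
    width and overlap fraction recorded in the session config.
    """
    if len(stimuli) == 0:
        raise ValueError("stimuli must contain at least one trial")
    if observer.model not in OBSERVER_MODELS:
        raise ValueError(f"unknown observer model {observer.model!r}; "
                         f"choose from {OBSERVER_MODELS}")
    cfg = _config_from(stimuli, config)
    likelihood_sd = observer.model_params.get("likelihood_sd", cfg.get("likelihood_sd", 0.1))
    p = observer.model_params

    if observer.model == "oracle_fixed_prior":
        prior_mean = p.get("prior_mean", stimuli["prior_mean_true"].to_numpy())
        prior_sd = p.get("prior_sd", stimuli["prior_sd_true"].to_numpy())
        gains = compute_gain(prior_sd, likelihood_sd)
        responses = optimal_estimate(prior_mean, stimuli["cue"].to_numpy(), gains)
        responses = np.asarray(responses, dtype=float)
    elif observer.model == "flat_prior_ml":
        responses = stimuli["cue"].to_numpy().copy()
    elif observer.model == "nig_learner":
        init = p.get("init", DEFAULT_NIG_INIT)
        if isinstance(init, dict):
            init = NIGState(**init)
        traj = run_nig_session(stimuli, init, likelihood_sd,
                               variance_mode=p.get("variance_mode", "mean"))
        responses = traj["response"].to_numpy()
    elif observer.model == "linear_filter":
        state = p.get("state")
        if state is None:
            state = LinearFilterState.initial(
                learning_rate=p.get("learning_rate", 0.1),
                var_init=p.get("var_init", 0.1),
                mean_init=p.get("mean_init", 0.0),
                window_size=p.get("window_size", 10),
                mean_mode=p.get("mean_mode", "all"))
        traj = run_lf_session(stimuli, state, likelihood_sd)
        responses = traj["response"].to_numpy()
    else:  # switching
        sw = p.get("config")
        if sw is None:
            if config is None and "config" in stimuli.attrs:
                config = SessionConfig.from_dict(dict(stimuli.attrs["config"]))
            if config is None:
                raise ValueError("switching observer needs a SessionConfig "
                                 "(pass config= or use stimuli from generate_session)")
            sw = SwitchModelConfig.from_session_config(
                config,
                **{k: p[k] for k in ("d_max", "constant_hazard", "placement") if k in p})
        traj = run_switch_session(stimuli, sw)
        responses = traj["response"].to_numpy()

    if observer.motor_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        responses = responses + observer.motor_noise_sd * rng.standard_normal(len(responses))

    out = stimuli.copy()
    out["response"] = responses
    out["caught"] = is_caught(responses, stimuli["target"].to_numpy(),
                              cfg.get("coin_width", 0.03),
                              cfg.get("catch_overlap_fraction", 0.5)).astype(float)
    out.attrs = dict(stimuli.attrs)
    out.attrs["observer"] = {"model": observer.model,
                             "motor_noise_sd": observer.motor_noise_sd}
    return out
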