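"""Stimulus generation for the three coin-catching protocols.

The synthetic-data generator reproduces the study's generative process:

* targets drawn from the session prior ``N(prior_mean_t, prior_sd_t^2)``,
* cues drawn around each target with fixed likelihood spread 0.1,
* screen coordinates normalised to [-0.5, 0.5] (positions are *not* clipped;
  Gaussian tails may fall off-screen unless ``redraw_offscreen`` is set),
* protocol 1: a constant prior (spread 0.05 or 0.2) with a random
  subject-specific mean ~ N(0, 0.1), 400 trials;
* protocol 2: as protocol 1 but the spread switches to the other value after
  trial 250, 500 trials;
* protocol 3: spread fixed at 0.1, mean flipping between -0.05 and +0.05
  under a 10-trial refractory period followed by per-trial Bernoulli(0.2)
  switching, 600 trials.

A session is a pandas DataFrame, one row per trial, that downstream observers
fill with responses.  One RNG seed per session is split into named substreams
(subject mean, switches, targets, cues) so adding an observer or toggling a
flag never perturbs the stimulus stream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "SessionConfig",
    "TRIAL_COLUMNS",
    "generate_session",
    "is_caught",
    "write_trial_log",
    "read_trial_log",
]

PROTOCOLS = ("exp1", "exp2", "exp3")

#: Column order of the trial-log CSV.
TRIAL_COLUMNS = [
    "trial_index",
    "prior_mean_true",
    "prior_sd_true",
    "target",
    "cue",
    "response",
    "caught",
    "trials_since_switch",
]


class ConfigError(ValueError):
    """Invalid session configuration."""


@dataclass(frozen=True)
class SessionConfig:
    """Full generative specification of one experimental session.

    ``prior_sd_schedule`` is a sequence of ``(start_trial, sd)`` pairs
    (1-based, strictly increasing, covering trial 1); each entry is in force
    until the next one starts.  The printed prior spreads 0.05 / 0.2 / 0.1
    are standard deviations — only that reading yields the optimal
    response-on-cue slopes 0.8 and 0.2 with likelihood spread 0.1.
    """

    protocol: str
    n_trials: int
    prior_sd_schedule: tuple
    likelihood_sd: float = 0.1
    prior_mean_mode: str = "random_subject_specific"
    subject_mean_sd: float = 0.1
    two_state_means: tuple = (-0.05, 0.05)
    refractory_trials: int = 10
    switch_prob: float = 0.2
    coin_width: float = 0.03
    catch_overlap_fraction: float = 0.5
    redraw_offscreen: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ConfigError(f"protocol must be one of {PROTOCOLS}, got {self.protocol!r}")
        if not self.n_trials > 0:
            raise ConfigError("n_trials must be > 0")
        if not self.likelihood_sd > 0:
            raise ConfigError("likelihood_sd must be > 0")
        if self.prior_mean_mode not in ("random_subject_specific", "two_state"):
            raise ConfigError(f"unknown prior_mean_mode {self.prior_mean_mode!r}")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ConfigError("switch_prob must lie in [0, 1]")
        if self.refractory_trials < 0:
            raise ConfigError("refractory_trials must be >= 0")
        if not self.coin_width > 0:
            raise ConfigError("coin_width must be > 0")
        sched = tuple((int(s), float(v)) for s, v in self.prior_sd_schedule)
        object.__setattr__(self, "prior_sd_schedule", sched)
        if not sched or sched[0][0] != 1:
            raise ConfigError("prior_sd_schedule must start at trial 1")
        starts = [s for s, _ in sched]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigError("prior_sd_schedule start trials must be strictly increasing")
        if any(v <= 0 for _, v in sched):
            raise ConfigError("all scheduled prior sds must be > 0")
        object.__setattr__(self, "two_state_means", tuple(float(m) for m in self.two_state_means))

    # ---------------------------------------------------------------- factories
    @classmethod
    def exp1(cls, prior_sd: float = 0.2, n_trials: int = 400, seed: int = 0, **kw) -> "SessionConfig":
        """Protocol 1: constant prior spread (wide 0.2 by default, narrow 0.05)."""
        return cls(protocol="exp1", n_trials=n_trials,
                   prior_sd_schedule=((1, prior_sd),), seed=seed, **kw)

    @classmethod
    def exp2(cls, first_sd: float = 0.2, second_sd: float | None = None,
             n_trials: int = 500, switch_trial: int = 251, seed: int = 0, **kw) -> "SessionConfig":
        """Protocol 2: the prior spread switches once after half the trials.

        Trial ``switch_trial`` is the first trial governed by the second
        spread.  With the defaults the switch is 0.2 -> 0.05 ("group 2A");
        pass ``first_sd=0.05`` for the 0.05 -> 0.2 order ("group 2B").
        """
        if second_sd is None:
            second_sd = 0.05 if first_sd == 0.2 else 0.2
        return cls(protocol="exp2", n_trials=n_trials,
                   prior_sd_schedule=((1, first_sd), (switch_trial, second_sd)),
                   seed=seed, **kw)

    @classmethod
    def exp3(cls, prior_sd: float = 0.1, n_trials: int = 600, seed: int = 0, **kw) -> "SessionConfig":
        """Protocol 3: mean flips between two known locations, spread fixed."""
        return cls(protocol="exp3", n_trials=n_trials,
                   prior_sd_schedule=((1, prior_sd),),
                   prior_mean_mode="two_state", seed=seed, **kw)

    # ---------------------------------------------------------------- serialisation
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prior_sd_schedule"] = [list(p) for p in self.prior_sd_schedule]
        d["two_state_means"] = list(self.two_state_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path) -> "SessionConfig":
        """Load a config from JSON or YAML (by extension; YAML otherwise)."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            d = json.loads(text)
        else:
            d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(d)

    # ---------------------------------------------------------------- helpers
    def prior_sd_per_trial(self) -> np.ndarray:
        """The scheduled prior sd for each of the ``n_trials`` trials."""
        out = np.empty(self.n_trials)
        sched = list(self.prior_sd_schedule) + [(self.n_trials + 1, np.nan)]
        for (start, sd), (nxt, _) in zip(sched, sched[1:]):
            out[start - 1:min(nxt, self.n_trials + 1) - 1] = sd
        return out


def _substreams(seed: int, n: int = 4) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _two_state_means(config: SessionConfig, rng: np.random.Generator):
    """Simulate the switching process: active mean and 1-based dwell per trial.

    A switch is possible only once ``refractory_trials`` trials have been
    completed in the current state; thereafter a flip occurs independently
    after each trial with probability ``switch_prob`` (so the minimum run
    length equals the refractory period and the mean run length is
    ``refractory - 1 + 1/switch_prob``).
    """
    means = np.empty(config.n_trials)
    dwell = np.empty(config.n_trials, dtype=int)
    idx = int(rng.integers(2))
    tss = 0
    for t in range(config.n_trials):
        tss += 1
        means[t] = config.two_state_means[idx]
        dwell[t] = tss
        if tss >= config.refractory_trials and rng.random() < config.switch_prob:
            idx = 1 - idx
            tss = 0
    return means, dwell


def generate_session(config: SessionConfig) -> pd.DataFrame:
    """Generate the stimulus stream (targets and cues) for one session.

    Returns a DataFrame with :data:`TRIAL_COLUMNS`; ``response`` and
    ``caught`` are NaN until an observer is run.  Bit-identical for a fixed
    config (including seed).
    """
    mean_rng, switch_rng, target_rng, cue_rng = _substreams(config.seed)

    prior_sd = config.prior_sd_per_trial()
    if config.prior_mean_mode == "random_subject_specific":
        mu = float(mean_rng.normal(0.0, config.subject_mean_sd))
        prior_mean = np.full(config.n_trials, mu)
        dwell = np.full(config.n_trials, np.nan)
    else:
        prior_mean, dwell = _two_state_means(config, switch_rng)

    targets = prior_mean + prior_sd * target_rng.standard_normal(config.n_trials)
    cues = targets + config.likelihood_sd * cue_rng.standard_normal(config.n_trials)
    if config.redraw_offscreen:
        for _ in range(100):
            bad = (np.abs(targets) > 0.5) | (np.abs(cues) > 0.5)
            if not bad.any():
                break
            n_bad = int(bad.sum())
            targets[bad] = prior_mean[bad] + prior_sd[bad] * target_rng.standard_normal(n_bad)
            cues[bad] = targets[bad] + config.likelihood_sd * cue_rng.standard_normal(n_bad)

    df = pd.DataFrame({
        "trial_index": np.arange(1, config.n_trials + 1),
        "prior_mean_true": prior_mean,
        "prior_sd_true": prior_sd,
        "target": targets,
        "cue": cues,
        "response": np.nan,
        "caught": np.nan,
        "trials_since_switch": dwell,
    })
    df.attrs["config"] = config.to_dict()
    return df


def is_caught(net, target, coin_width: float, overlap_fraction: float = 0.5):
    """Whether a thin vertical net at ``net`` catches a coin at ``target``.

    The net is a zero-width line, so the >= ``overlap_fraction`` overlap rule
    for a coin of width ``coin_width`` reduces to the distance threshold
    ``|net - target| <= (1 - overlap_fraction) * coin_width`` (boundary
    inclusive).
    """
    if not coin_width > 0:
        raise ValueError("coin_width must be > 0")
    d = np.abs(np.asarray(net, dtype=float) - np.asarray(target, dtype=float))
    out = d <= (1.0 - overlap_fraction) * coin_width
    if out.ndim == 0:
        return bool(out)
    return out


# ---------------------------------------------------------------------- CSV I/O

def write_trial_log(df: pd.DataFrame, path) -> None:
    """Write a trial log CSV (positions at 9 significant digits, empty string
    for absent response/caught fields)."""
    out = df.loc[:, TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.9g")


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} is missing columns: {missing}")
    return df
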