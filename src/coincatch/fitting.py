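"""Model comparison: fit observer models to binned learning curves.

The observable a model must explain is a pair of across-subject average
learning curves from protocol 1 (wide-prior and narrow-prior groups): per
10-trial bin, the mean prior-mean error and the mean gain ``r`` with their
across-subject standard errors.  A candidate observer model is scored by
the log likelihood of those binned observations under independent Gaussian
errors with the empirical per-bin SEs,

    ll = sum_bins sum_{mu_err, r} log N(observed; model average, SE),

where the model averages come from simulating many sessions of the same
protocols.  Common random numbers (stimuli pre-generated once per model
instance) make the objective deterministic given the seed, so a
derivative-free simplex search with restarts is well behaved.

Two model classes are provided in the statsmodels idiom (construct from
data, ``fit()`` returns a results object with parameters, likelihood,
diagnostics and ``summary()``):

* :class:`NIGCurveModel` — four free parameters, the NIG learner's initial
  hyperparameters ``(mu0, lam0, alpha0, beta0)``;
* :class:`LinearFilterCurveModel` — two free parameters, the filter's
  learning rate and initial variance.

Held-out discipline is structural: models are *fitted* to protocol-1
curves only; protocol-2 curves enter only through ``Results.predict`` /
:func:`rms_error`, never the objective.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import batch
from .nig import NIGState
from .observers import ObserverSpec, run_observer
from .task import SessionConfig, generate_session

__all__ = [
    "FitTarget",
    "cohort_curves",
    "make_fit_target",
    "curve_loglik",
    "NIGCurveModel",
    "LinearFilterCurveModel",
    "CurveFitResults",
    "rms_error",
    "r_squared",
]

CURVE_COLUMNS = ["bin_index", "mu_err", "gain", "se_mu_err", "se_gain"]


# --------------------------------------------------------------------- targets

def cohort_curves(config: SessionConfig, observer: ObserverSpec,
                  n_subjects: int = 7, seed: int = 0, bin_size: int = 10,
                  se_floor: float = 1e-3) -> pd.DataFrame:
    """Across-subject average binned curves from a simulated cohort.

    Each synthetic subject gets an independent session (fresh subject mean)
    and an independent motor-noise stream; the per-subject binned OLS
    estimates (gain and prior-mean error) are averaged across subjects.
    Degenerate (flat-prior) bins contribute to the gain average but are
    excluded from the mean-error average.  SEs are floored at ``se_floor``
    to keep the Gaussian error model proper.
    """
    from .analysis import bin_series

    rs, mus = [], []
    roots = np.random.SeedSequence(seed).spawn(n_subjects)
    for i, root in enumerate(roots):
        s_stim, s_motor = (int(c.generate_state(1)[0] % (2 ** 31)) for c in root.spawn(2))
        cfg = SessionConfig.from_dict({**config.to_dict(), "seed": s_stim})
        log = run_observer(generate_session(cfg), observer, seed=s_motor)
        binned = bin_series(log, bin_size=bin_size)
        rs.append(binned["r"].to_numpy())
        mus.append(binned["mu_p_error"].to_numpy())
    r = np.vstack(rs)
    mu = np.vstack(mus)
    n_mu = np.sum(~np.isnan(mu), axis=0)
    with np.errstate(invalid="ignore"):
        mu_mean = np.nanmean(mu, axis=0)
        mu_se = np.nanstd(mu, axis=0, ddof=1) / np.sqrt(np.maximum(n_mu, 1))
    mu_mean = np.where(n_mu >= 2, mu_mean, 0.0)      # all-degenerate bin: uninformative
    mu_se = np.where(n_mu >= 2, mu_se, np.inf)
    return pd.DataFrame({
        "bin_index": np.arange(1, r.shape[1] + 1),
        "mu_err": mu_mean,
        "gain": r.mean(axis=0),
        "se_mu_err": np.maximum(mu_se, se_floor),
        "se_gain": np.maximum(r.std(axis=0, ddof=1) / np.sqrt(r.shape[0]), se_floor),
    })


@dataclass(frozen=True)
class FitTarget:
    """The fitting observable: wide- and narrow-prior protocol-1 curves."""

    wide: pd.DataFrame
    narrow: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("wide", self.wide), ("narrow", self.narrow)):
            missing = [c for c in CURVE_COLUMNS if c not in df.columns]
            if missing:
                raise ValueError(f"{name} curve missing columns {missing}")
            if not (df["se_gain"] > 0).all() or not (df["se_mu_err"] > 0).all():
                raise ValueError(f"{name} curve has non-positive SEs")

    def to_json(self, path) -> None:
        payload = {"wide": self.wide[CURVE_COLUMNS].to_dict(orient="list"),
                   "narrow": self.narrow[CURVE_COLUMNS].to_dict(orient="list")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitTarget":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(wide=pd.DataFrame(payload["wide"]),
                   narrow=pd.DataFrame(payload["narrow"]))


def make_fit_target(wide_config: SessionConfig, narrow_config: SessionConfig,
                    observer: ObserverSpec, n_subjects: int = 7,
                    seed: int = 0) -> FitTarget:
    """Simulate a synthetic-subject cohort per group and bundle the curves."""
    return FitTarget(
        wide=cohort_curves(wide_config, observer, n_subjects, seed=seed),
        narrow=cohort_curves(narrow_config, observer, n_subjects, seed=seed + 1),
    )


# ------------------------------------------------------------------- likelihood

def curve_loglik(model_curve: pd.DataFrame, target_curve: pd.DataFrame) -> float:
    """Gaussian log likelihood of a target curve under a model curve.

    Sums over bins and both observables (mean error and gain), each with the
    target's per-bin SE.  Bins with non-finite SEs (uninformative) are
    skipped.  Bin structures must match.
    """
    if len(model_curve) != len(target_curve):
        raise ValueError(f"bin mismatch: model has {len(model_curve)}, "
                         f"target has {len(target_curve)}")
    total = 0.0
    for obs_col, se_col in (("mu_err", "se_mu_err"), ("gain", "se_gain")):
        x = target_curve[obs_col].to_numpy(dtype=float)
        m = model_curve[obs_col].to_numpy(dtype=float)
        se = target_curve[se_col].to_numpy(dtype=float)
        ok = np.isfinite(se) & np.isfinite(x)
        z = (x[ok] - m[ok]) / se[ok]
        total += float(np.sum(-0.5 * z ** 2 - np.log(se[ok]) - 0.5 * np.log(2 * np.pi)))
    return total


def rms_error(model_curves, target_curves, field: str = "gain") -> float:
    """Pooled RMS of bin-wise differences across one or more curve pairs."""
    if isinstance(model_curves, pd.DataFrame):
        model_curves, target_curves = [model_curves], [target_curves]
    diffs = []
    for m, t in zip(model_curves, target_curves):
        if len(m) != len(t):
            raise ValueError("bin mismatch in rms_error")
        diffs.append(m[field].to_numpy(dtype=float) - t[field].to_numpy(dtype=float))
    d = np.concatenate(diffs)
    return float(np.sqrt(np.mean(d ** 2)))


def r_squared(model_curve, target_curve, field: str = "mean_estimate") -> float:
    """Coefficient of determination of a target curve against a model curve:
    ``1 - SS_res / SS_tot`` (SS_tot about the target's mean)."""
    y = np.asarray(target_curve[field] if hasattr(target_curve, "__getitem__")
                   else target_curve, dtype=float)
    m = np.asarray(model_curve[field] if hasattr(model_curve, "__getitem__")
                   else model_curve, dtype=float)
    ss_res = float(np.sum((y - m) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


# ------------------------------------------------------------------ model layer

class _CurveModelBase:
    """Shared machinery: CRN stimuli, simplex fit with restarts."""

    param_names: tuple[str, ...] = ()

    def __init__(self, target: FitTarget, wide_config: SessionConfig,
                 narrow_config: SessionConfig, n_runs: int = 500, seed: int = 0,
                 bin_size: int = 10):
        self.target = target
        self.configs = {"wide": wide_config, "narrow": narrow_config}
        self.n_runs = int(n_runs)
        self.seed = int(seed)
        self.bin_size = int(bin_size)
        # Common random numbers: stimuli drawn once, reused by every objective
        # evaluation, so the objective is a deterministic function of params.
        self._stimuli = {
            name: batch.batch_stimuli(cfg, self.n_runs, seed=self.seed + i)
            for i, (name, cfg) in enumerate(self.configs.items())
        }

    # per-subclass
    def _curves(self, params: dict, which: str) -> pd.DataFrame:
        raise NotImplementedError

    def _to_theta(self, params: dict) -> np.ndarray:
        raise NotImplementedError

    def _from_theta(self, theta: np.ndarray) -> dict:
        raise NotImplementedError

    def _starts(self, rng: np.random.Generator, restarts: int) -> list[np.ndarray]:
        raise NotImplementedError

    def model_curves(self, params: dict) -> dict:
        return {name: self._curves(params, name) for name in self.configs}

    def loglik(self, params: dict) -> float:
        curves = self.model_curves(params)
        return (curve_loglik(curves["wide"], self.target.wide)
                + curve_loglik(curves["narrow"], self.target.narrow))

    def fit(self, restarts: int = 5, maxfev: int = 250,
            fatol: float = 1e-3, xatol: float = 1e-3) -> "CurveFitResults":
        """Maximise the curve log likelihood by Nelder-Mead with restarts.

        Parameters are searched in an unconstrained transform space
        (log / logit for positive / bounded parameters).  Non-convergence is
        flagged on the results object, not raised.
        """
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1_000_003]))
        trace = []

        def negll(theta: np.ndarray) -> float:
            ll = self.loglik(self._from_theta(theta))
            trace.append((theta.copy(), ll))
            return -ll

        best = None
        for theta0 in self._starts(rng, restarts):
            res = optimize.minimize(negll, theta0, method="Nelder-Mead",
                                    options={"maxfev": maxfev, "fatol": fatol,
                                             "xatol": xatol})
            if best is None or res.fun < best.fun:
                best = res
        params = self._from_theta(best.x)
        return CurveFitResults(model=self, params=params, llf=-float(best.fun),
                               converged=bool(best.success), nfev=int(len(trace)),
                               trace=trace)


class NIGCurveModel(_CurveModelBase):
    """Fit the NIG learner's four initial hyperparameters to protocol-1 curves.

    ``alpha0`` is constrained above 1 (so the initial variance estimate
    exists) and ``lam0``, ``beta0`` above 0 via log transforms.
    """

    param_names = ("mu0", "lam0", "alpha0", "beta0")

    def __init__(self, *args, variance_mode: str = "mean", **kw):
        super().__init__(*args, **kw)
        self.variance_mode = variance_mode

    def _curves(self, params: dict, which: str) -> pd.DataFrame:
        init = NIGState(params["mu0"], params["lam0"], params["alpha0"], params["beta0"])
        stim = self._stimuli[which]
        traj = batch.batch_nig(stim["target"], stim["cue"], init,
                               self.configs[which].likelihood_sd,
                               variance_mode=self.variance_mode)
        return batch.curves_from_trajectories(traj["mu"] - stim["prior_mean"],
                                              traj["gain"], self.bin_size)

    def _to_theta(self, p: dict) -> np.ndarray:
        return np.array([p["mu0"], np.log(p["lam0"]),
                         np.log(p["alpha0"] - 1.0), np.log(p["beta0"])])

    def _from_theta(self, t: np.ndarray) -> dict:
        return {"mu0": float(t[0]), "lam0": float(np.exp(t[1])),
                "alpha0": 1.0 + float(np.exp(t[2])), "beta0": float(np.exp(t[3]))}

    def _starts(self, rng, restarts):
        base = self._to_theta({"mu0": 0.0, "lam0": 1.0, "alpha0": 1.2, "beta0": 0.02})
        starts = [base]
        for _ in range(max(restarts - 1, 0)):
            starts.append(base + rng.normal(0.0, [0.05, 0.7, 0.7, 0.7]))
        return starts


class LinearFilterCurveModel(_CurveModelBase):
    """Fit the linear filter's (learning_rate, var_init) to protocol-1 curves."""

    param_names = ("learning_rate", "var_init")

    def __init__(self, *args, window: int = 10, mean_mode: str = "all", **kw):
        super().__init__(*args, **kw)
        self.window = window
        self.mean_mode = mean_mode

    def _curves(self, params: dict, which: str) -> pd.DataFrame:
        stim = self._stimuli[which]
        traj = batch.batch_linear_filter(stim["target"], stim["cue"],
                                         params["learning_rate"], params["var_init"],
                                         self.configs[which].likelihood_sd,
                                         window=self.window, mean_mode=self.mean_mode)
        return batch.curves_from_trajectories(traj["mean"] - stim["prior_mean"],
                                              traj["gain"], self.bin_size)

    def _to_theta(self, p: dict) -> np.ndarray:
        rate = min(max(p["learning_rate"], 1e-6), 1 - 1e-6)
        return np.array([np.log(rate / (1.0 - rate)), np.log(p["var_init"])])

    def _from_theta(self, t: np.ndarray) -> dict:
        return {"learning_rate": float(1.0 / (1.0 + np.exp(-t[0]))),
                "var_init": float(np.exp(t[1]))}

    def _starts(self, rng, restarts):
        base = self._to_theta({"learning_rate": 0.1, "var_init": 0.1})
        starts = [base]
        for _ in range(max(restarts - 1, 0)):
            starts.append(base + rng.normal(0.0, [1.0, 0.7]))
        return starts


@dataclass
class CurveFitResults:
    """Fitted parameters plus diagnostics; prediction of held-out protocols."""

    model: _CurveModelBase
    params: dict
    llf: float
    converged: bool
    nfev: int
    trace: list = field(repr=False, default_factory=list)

    def predict(self, config: SessionConfig, n_runs: int | None = None,
                seed: int | None = None) -> pd.DataFrame:
        """Average model curves for an arbitrary protocol (e.g. protocol 2)
        at the fitted parameters — the held-out prediction path."""
        n_runs = n_runs or self.model.n_runs
        seed = self.model.seed + 10_000 if seed is None else seed
        stim = batch.batch_stimuli(config, n_runs, seed=seed)
        if isinstance(self.model, NIGCurveModel):
            init = NIGState(self.params["mu0"], self.params["lam0"],
                            self.params["alpha0"], self.params["beta0"])
            traj = batch.batch_nig(stim["target"], stim["cue"], init,
                                   config.likelihood_sd,
                                   variance_mode=self.model.variance_mode)
            mu = traj["mu"]
        else:
            traj = batch.batch_linear_filter(stim["target"], stim["cue"],
                                             self.params["learning_rate"],
                                             self.params["var_init"],
                                             config.likelihood_sd,
                                             window=self.model.window,
                                             mean_mode=self.model.mean_mode)
            mu = traj["mean"]
        return batch.curves_from_trajectories(mu - stim["prior_mean"], traj["gain"],
                                              self.model.bin_size)

    def summary(self) -> str:
        lines = [f"{type(self.model).__name__} fit",
                 "=" * 40,
                 f"log-likelihood: {self.llf:.3f}",
                 f"objective evaluations: {self.nfev}",
                 f"converged: {self.converged}",
                 f"simulated runs per evaluation: {self.model.n_runs}",
                 f"seed: {self.model.seed}",
                 "-" * 40]
        for name in self.model.param_names:
            lines.append(f"{name:>14s}: {self.params[name]: .6g}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {"model": type(self.model).__name__, "params": self.params,
                   "llf": self.llf, "converged": self.converged,
                   "nfev": self.nfev, "n_runs": self.model.n_runs,
                   "seed": self.model.seed}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
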