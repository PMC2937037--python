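"""Learning-curve measurement from trial logs.

A trial log (simulated observer or imported data) only exposes cue and
response positions.  Because the optimal placement is linear in the cue,
``response = (1 - r) mu_p + r cue``, ordinary least squares of response on
cue within a bin of consecutive trials recovers the gain ``r`` (slope) and
the believed prior mean ``mu_p = intercept / (1 - r)``.  Binning every 10
consecutive trials turns a session into the learning curves:

* per-bin gain ``r`` — converges to sigma_p^2/(sigma_p^2 + sigma_l^2);
* per-bin prior-mean error — converges to 0 within the first bin or two;
* the reconstructed prior per bin (via the known likelihood spread).

For the switching protocol, trials are re-sorted by their index relative to
the most recent mean switch and the per-trial implied prior mean
``(response - r_hat cue) / (1 - r_hat)`` is averaged across switches, which
exposes adaptation at single-trial resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaussian import FLAT_PRIOR, GaussianSpec, reconstruct_prior

__all__ = [
    "BinFit",
    "fit_bin",
    "bin_series",
    "align_to_switches",
    "steady_state_gain",
    "prior_trajectory",
]

#: |1 - r| below which the intercept-to-mean inversion is unidentifiable.
DEGENERATE_TOL = 0.05
#: Fitted gains outside this band are flagged as suspect.
R_FLAG_RANGE = (-0.2, 1.2)


@dataclass(frozen=True)
class BinFit:
    r: float
    mu_p: float                 # NaN when degenerate (flat-prior regime)
    residual_rms: float
    degenerate: bool
    n: int


def fit_bin(cues, responses) -> BinFit:
    """OLS of response on cue: slope = r, intercept = (1 - r) mu_p.

    Requires >= 3 trials and non-degenerate cue spread (identical cues are a
    singular design).  When the slope is within ``DEGENERATE_TOL`` of 1 the
    prior mean is unidentifiable: the bin is flagged degenerate and ``mu_p``
    reported as NaN (the flat-prior sentinel).
    """
    c = np.asarray(cues, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.size < 3:
        raise ValueError(f"need at least 3 trials per bin, got {c.size}")
    sxx = float(((c - c.mean()) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("all cues identical: singular design, cannot fit r")
    r = float(((c - c.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - r * c.mean())
    resid = y - (intercept + r * c)
    degenerate = abs(1.0 - r) < DEGENERATE_TOL
    mu_p = math.nan if degenerate else intercept / (1.0 - r)
    return BinFit(r=r, mu_p=mu_p, residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                  degenerate=degenerate, n=int(c.size))


def bin_series(log: pd.DataFrame, bin_size: int = 10) -> pd.DataFrame:
    """Fit (r, mu_p) in consecutive non-overlapping bins of ``bin_size`` trials.

    A trailing partial bin is dropped (with a warning).  When the log carries
    generative truth columns, ``mu_p_error = mu_p - mean(prior_mean_true)``
    per bin is included.  Gains outside ``R_FLAG_RANGE`` set ``r_flagged``.
    """
    n = len(log)
    if n < bin_size:
        raise ValueError(f"log has {n} trials, need at least one bin of {bin_size}")
    n_bins = n // bin_size
    dropped = n - n_bins * bin_size
    if dropped:
        warnings.warn(f"dropping trailing partial bin of {dropped} trials")
    cues = log["cue"].to_numpy()[:n_bins * bin_size]
    resp = log["response"].to_numpy()[:n_bins * bin_size]
    have_truth = "prior_mean_true" in log.columns and log["prior_mean_true"].notna().all()
    truth = log["prior_mean_true"].to_numpy()[:n_bins * bin_size] if have_truth else None
    rows = []
    for b in range(n_bins):
        s = slice(b * bin_size, (b + 1) * bin_size)
        fit = fit_bin(cues[s], resp[s])
        row = {"bin_index": b + 1, "r": fit.r, "mu_p": fit.mu_p,
               "residual_rms": fit.residual_rms, "degenerate": fit.degenerate,
               "r_flagged": not (R_FLAG_RANGE[0] <= fit.r <= R_FLAG_RANGE[1])}
        if truth is not None:
            row["mu_p_error"] = fit.mu_p - truth[s].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def steady_state_gain(log: pd.DataFrame, last_n: int = 200,
                      remove_mean: bool | str = "auto") -> tuple[float, float]:
    """Gain fitted to the last ``last_n`` trials as a single block: ``(r, SE)``.

    ``remove_mean`` subtracts the per-trial true prior mean from cue and
    response before fitting, so that mean switching (protocol 3) does not
    inflate the slope; ``"auto"`` removes it whenever the log contains more
    than one true mean.  Without removal the active mean contributes
    covariance between cue and response and the pooled slope overestimates
    the within-state gain.
    """
    if last_n > len(log):
        raise ValueError(f"last_n={last_n} exceeds log length {len(log)}")
    tail = log.iloc[-last_n:]
    c = tail["cue"].to_numpy(dtype=float)
    y = tail["response"].to_numpy(dtype=float)
    if remove_mean == "auto":
        remove_mean = ("prior_mean_true" in tail.columns
                       and tail["prior_mean_true"].nunique() > 1)
    if remove_mean:
        m = tail["prior_mean_true"].to_numpy(dtype=float)
        c = c - m
        y = y - m
    cm, ym = c.mean(), y.mean()
    sxx = float(((c - cm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("all cues identical: singular design")
    r = float(((c - cm) * (y - ym)).sum() / sxx)
    resid = y - (ym - r * cm) - r * c
    dof = max(len(c) - 2, 1)
    se = float(np.sqrt(resid @ resid / dof / sxx))
    return r, se


def align_to_switches(log: pd.DataFrame, r_hat: float | None = None,
                      k_max: int = 10, last_n: int = 200) -> pd.DataFrame:
    """Switch-locked trial-by-trial estimate of the believed prior mean.

    Groups trials by trials-since-switch ``k = 1..k_max`` across all
    switches (the pre-first-switch segment is excluded), inverting the
    placement rule per trial with a fixed gain ``r_hat`` (defaulting to
    :func:`steady_state_gain` over the last ``last_n`` trials).  Columns:

    ``k, mean_estimate, se, n_switches`` and, when truth columns exist,
    ``aligned_estimate``: the implied mean re-signed toward the newly active
    mean (positive = moved toward the new mean), which does not cancel when
    averaging switches in both directions.

    Returns an empty DataFrame (the empty-curve sentinel) when the log
    contains no switches.
    """
    cols = ["k", "mean_estimate", "se", "n_switches", "aligned_estimate", "aligned_se"]
    if "trials_since_switch" not in log.columns or log["trials_since_switch"].isna().all():
        return pd.DataFrame(columns=cols)
    tss = log["trials_since_switch"].to_numpy(dtype=float)
    # A switch boundary is any later trial whose dwell counter restarts at 1.
    switch_starts = np.flatnonzero((tss == 1) & (np.arange(len(tss)) > 0))
    if switch_starts.size == 0:
        return pd.DataFrame(columns=cols)
    if r_hat is None:
        r_hat, _ = steady_state_gain(log, last_n=min(last_n, len(log)))
    if abs(1.0 - r_hat) < DEGENERATE_TOL:
        raise ValueError("r_hat too close to 1: implied-mean inversion is degenerate")
    cue = log["cue"].to_numpy(dtype=float)
    resp = log["response"].to_numpy(dtype=float)
    implied = (resp - r_hat * cue) / (1.0 - r_hat)
    have_truth = "prior_mean_true" in log.columns and log["prior_mean_true"].notna().all()
    if have_truth:
        mean_true = log["prior_mean_true"].to_numpy(dtype=float)
        mid = (np.min(mean_true) + np.max(mean_true)) / 2.0
    first_switch = switch_starts[0]
    rows = []
    for k in range(1, k_max + 1):
        sel = np.flatnonzero((tss == k) & (np.arange(len(tss)) >= first_switch))
        if sel.size == 0:
            continue
        vals = implied[sel]
        row = {"k": k, "mean_estimate": float(vals.mean()),
               "se": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else math.nan,
               "n_switches": int(vals.size)}
        if have_truth:
            sign = np.sign(mean_true[sel] - mid)
            av = (implied[sel] - mid) * sign
            row["aligned_estimate"] = float(av.mean())
            row["aligned_se"] = (float(av.std(ddof=1) / np.sqrt(av.size))
                                 if av.size > 1 else math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def prior_trajectory(binned: pd.DataFrame, likelihood_sd: float) -> list[GaussianSpec]:
    """Reconstructed prior per bin; degenerate bins yield flat-prior sentinels."""
    out = []
    for _, row in binned.iterrows():
        if row.get("degenerate", False) or row["r"] >= 1.0:
            out.append(GaussianSpec(mean=row["mu_p"], sd=math.inf, flat=True))
        elif row["r"] < 0.0:
            out.append(FLAT_PRIOR if not np.isfinite(row["mu_p"])
                       else GaussianSpec(mean=row["mu_p"], sd=0.0))
        else:
            out.append(reconstruct_prior(row["r"], row["mu_p"], likelihood_sd))
    return out
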