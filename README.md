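# coincatch

Simulation and ideal-observer analysis of a one-dimensional "coin catching"
estimation task used to study how people *learn priors*.

On every trial a target coin is drawn from a Gaussian prior over horizontal
screen positions (screen normalised to [−0.5, 0.5]) and a visible cue coin is
drawn around the target with fixed likelihood spread σ_l = 0.1.  An observer
who knows both distributions should place the net at the posterior mean

    μ_t = (1 − r) μ_p + r μ_l,        r = σ_p² / (σ_p² + σ_l²),

where r — an alternate form of the Kalman gain — is also the slope of the
response-on-cue regression.  A learner who does *not* know the prior must
estimate μ_p and σ_p² from the revealed targets; watching the fitted (r, μ_p)
evolve over 10-trial bins exposes the learner's prior, trial by trial.

The package provides, as tested library code:

* **`task`** — generators for the three protocols: constant prior
  (400 trials, σ_p ∈ {0.05, 0.2}), a mid-session variance switch
  (500 trials), and a mean that flips between ±0.05 under a 10-trial
  refractory period plus per-trial Bernoulli(0.2) hazard (600 trials);
* **`observers`** — synthetic subjects: the fixed-prior oracle, the
  maximum-likelihood (flat-prior) baseline, a conjugate
  Normal-scaled-Inverse-Gamma (NIG) learner of the prior's mean and
  variance, a fixed-learning-rate linear filter that only tracks the
  variance, and an exact change-point (hidden semi-Markov) observer for the
  switching-mean protocol;
* **`analysis`** — the binned least-squares read-out, switch-aligned
  trial-by-trial mean estimates, steady-state gain, and reconstruction of
  the implied prior from fitted gains;
* **`fitting`** — statsmodels-style model objects (`NIGCurveModel`,
  `LinearFilterCurveModel`) that fit observer hyperparameters to binned
  learning curves by maximum likelihood with common random numbers, predict
  held-out protocols, and score models by RMS error;
* **`cli`** — a `coincatch` command with `simulate`, `analyze`, `fit` and
  `reproduce` subcommands writing CSV outputs plus a reproducibility
  manifest.

## Worked example

Run the NIG learner through a narrow-prior session and read its prior back
out of its behaviour:

```python
import coincatch as cc

cfg = cc.SessionConfig.exp1(prior_sd=0.05, seed=42)
log = cc.run_observer(cc.generate_session(cfg),
                      cc.ObserverSpec("nig_learner"), config=cfg)
binned = cc.bin_series(log)
print(binned.head(4))
```

```
 bin_index        r     mu_p  residual_rms  degenerate  r_flagged  mu_p_error
         1 0.587421 0.003409      0.017108       False      False   -0.038424
         2 0.336436 0.024046      0.003006       False      False   -0.017787
         3 0.283513 0.032550      0.001389       False      False   -0.009283
         4 0.316044 0.042460      0.002783       False      False    0.000627
```

The learner starts cue-dominated (r ≈ 0.59 in the first bin, falling from a
near-flat prior) and converges: by the final bins r ≈ 0.21, close to the
optimal 0.2 for σ_p = 0.05, and the prior-mean error shrinks to ~0.002
within a few bins.  Reconstructing the prior from the last bin gives

```python
cc.prior_trajectory(binned, likelihood_sd=0.1)[-1]
# GaussianSpec(mean=0.0394, sd=0.0520)   — generative prior: mean 0.0394, sd 0.05
```

The same pipeline from the shell:

```sh
coincatch simulate --config cfg.json --observer nig_learner --out run/
coincatch analyze run/trials.csv --out run/
coincatch reproduce fig6-model --out figs/
```

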