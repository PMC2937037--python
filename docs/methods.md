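# Methods

## Task and generative model

All positions live in normalised screen units, the screen spanning
[−0.5, 0.5].  Per trial, a target is drawn from the session prior
N(μ_p, σ_p²) and a cue from the likelihood N(target, σ_l²) with σ_l = 0.1
fixed and assumed known by every observer.  Positions are **not** clipped to
the screen: truncation would distort the Gaussian model, and the tails at
these spreads are negligible; a `redraw_offscreen` flag enables
truncation-by-redraw for sensitivity checks.

The printed prior spreads (0.05 and 0.2 for protocols 1–2, 0.1 for
protocol 3) are treated as **standard deviations**: only that reading yields
the optimal response-on-cue slopes 0.8 and 0.2 with σ_l = 0.1, which is the
anchor every downstream quantity is calibrated against.  Config keys are
named `*_sd` to make the commitment explicit.

Protocol defaults:

| protocol | trials | prior mean | prior sd |
|---|---|---|---|
| exp1 | 400 | per-subject, ~N(0, 0.1) | 0.05 or 0.2, constant |
| exp2 | 500 | per-subject, ~N(0, 0.1) | switches to the other value at trial 251 |
| exp3 | 600 | flips between −0.05 and +0.05 | 0.1, constant |

Protocol-3 switching: after a switch, flips are disallowed until
`refractory_trials = 10` trials have been completed in the current state;
thereafter a flip occurs independently after each trial with probability
`switch_prob = 0.2`.  The minimum run length is therefore 10 trials and the
mean run length is `(refractory − 1) + 1/switch_prob = 14` trials (run
length = 9 + Geometric(0.2)); the dwell test checks that closed form.

The catch rule models the net as a zero-width vertical line, so the
"overlap ≥ half a coin width" criterion reduces to
|net − target| ≤ (1 − overlap) · coin width, boundary inclusive.  No coin
width is dictated by the task geometry; the default 0.03 screen units is a
configurable package choice sized so that oracle observers catch a
realistic minority of coins.

One seed per session is split into named substreams (subject mean,
switches, targets, cues; motor noise has its own seed in `run_observer`),
so adding or swapping an observer never perturbs the stimulus stream, and
identical configs are bit-reproducible.

## Observers

All observers respond to the cue *before* seeing the trial's target
(respond-then-update); responding with current-trial target information
would be acausal.  Because the target is fully revealed each trial and the
cue is conditionally independent of the prior given the target, learning
observers update on the target only — the cue enters through the response.

**Fixed-prior oracle** — plugs the true generative (μ_p, σ_p) of each trial
into the linear rule; the Bayes-optimal benchmark.  **Flat-prior ML** —
responds at the cue (gain 1), the behaviour implied by an uninformative
prior.

**NIG learner** (protocols 1–2).  Joint belief over (μ_p, σ_p²) as a
Normal-scaled-Inverse-Gamma: σ² ~ InvGamma(α, β), μ | σ² ~ N(μ₀, σ²/λ).
Conjugate updates per revealed target x:

    μ' = (λμ + x)/(λ + 1),   λ' = λ + 1,
    α' = α + 1/2,            β' = β + λ(x − μ)²/(2(λ + 1)).

The four *initial* hyperparameters are the model's free parameters.  The
response plugs the posterior point estimates into the linear rule:
mean estimate μ, variance estimate E[σ²] = β/(α − 1) (requires α > 1; the
posterior mode β/(α + 1) and the Student-t posterior-predictive variance
β(λ + 1)/(λ(α − 1)) are switchable alternatives — they differ only by
Jensen-gap terms that vanish as λ, α grow).  The default reference init
(μ₀ = 0, λ₀ = 1, α₀ = 1.2, β₀ = 0.02 → initial variance estimate 0.1, gain
≈ 0.91) encodes the near-flat prior observers start with.  The model is a
pure conjugate accumulator by design: its growing certainty (λ, α increase
every trial) is the mechanism that slows late-session learning, and no
forgetting is added.

**Linear filter** (comparison model).  Tracks only the variance: the
unbiased sample variance of the last 10 targets is blended into the running
estimate with a constant learning rate, `var' = var + rate·(obs − var)`,
updated every trial once the window is full (the update cadence is not
dictated by the model description; per-trial sliding-window updating is
adopted).  Before the window fills, the estimate stays at `var_init`.  Its
mean estimate is not part of the model proper; the default is the running
mean of all observed targets (switchable to the window mean), which keeps
the model's diagnostic failure specific to variance dynamics.  Free
parameters: (rate, var_init); the window length is fixed at 10.

**Change-point observer** (protocol 3).  Knows σ_p, both candidate means
and the switching process; infers only which mean is active.  Because the
hazard depends on dwell time, the exact filter runs over joint
(mean, dwell) states with the hazard h(d) = 0 for d < 10, 0.2 otherwise
(a constant-hazard approximation is available behind a flag).  Dwell is
capped at d_max = 60; since the hazard is constant beyond the refractory
period, the cap bin is exact, not an approximation.  Placement conditions
the belief on the cue through its marginal likelihood
N(cue; mean_m, σ_p² + σ_l²) and takes the posterior-mean placement under
the two-component mixture (minimises expected squared error, consistent
with the estimation framing; MAP placement is a flag); the persistent
belief update uses the target only, so the cue is never double-counted.
The forward recursion is verified against exhaustive enumeration over
admissible mean sequences.

## Measurement

Within each 10-trial bin, OLS of response on cue gives r (slope) and
μ_p = intercept/(1 − r).  When |1 − r| < 0.05 the inversion is
unidentifiable and the bin is flagged degenerate (flat-prior sentinel)
rather than reported as a wild μ_p.  Trailing partial bins are dropped (all
protocol lengths are multiples of 10, so this only affects user data).
Reconstruction inverts the gain formula, σ_p = σ_l·sqrt(r/(1 − r)); r ≥ 1
maps to an infinite-spread flat-prior sentinel rather than an error, since
early-session gains near 1 are expected behaviour.

Switch-aligned analysis (protocol 3): trials are grouped by
trials-since-switch k = 1..10 across all switches, and the per-trial
implied mean (response − r̂·cue)/(1 − r̂) is averaged across switches with
r̂ fixed at the steady-state gain — single-trial joint (r, μ) fits are
ill-posed.  Because switches go in both directions, the curve is also
reported re-signed toward the newly active mean ("aligned"), which is what
the midpoint-crossing statistic uses.

Steady-state gain pools the last 200 trials into one OLS block.  For the
switching protocol the per-trial true mean is removed first (by default):
without removal the active mean contributes covariance between cue and
response and the pooled slope *over*-estimates the within-state gain
(≈ 0.56 vs ≈ 0.54 on change-point-observer logs against the generative
0.5); both modes are exposed so the confound can be quantified rather than
hidden.

## Model fitting

The fitting observable is the across-subject average binned curve pair
(mean μ_p error and mean gain per bin, with across-subject SEs) from the
two protocol-1 groups.  The likelihood treats bins and both observables as
independent Gaussians at the empirical SEs — the natural error model for
across-subject means; SE weighting is the default and pooled alternatives
can be swapped in through the target curves.  Model curves are the
bin-averaged *internal* trajectories (mean error and gain) over many
simulated sessions, matching how a simulated model's "average estimates"
are naturally reported; subject-side curves come from the binned OLS
read-out.

Optimisation is Nelder-Mead over unconstrained transforms (log for λ₀, β₀,
var_init; log(α₀ − 1) keeps the variance estimate defined; logit for the
learning rate) with 5 restarts by default, maxfev 250, tolerance 1e-3.
Stimuli are pre-generated once per model instance (common random numbers),
so the objective is a deterministic function of the parameters given the
seed and n_runs, and a non-convergent optimiser run flags the results
object instead of raising.  Held-out discipline is structural: the model
objects only ever see protocol-1 targets; protocol-2 curves enter through
`Results.predict` and `rms_error` only.

## Synthetic cohorts, and what the tests do and do not show

No behavioural data ships with the package; "subjects" are parameterised
observers.  The reference cohort is an NIG learner with a weakly informed
init (μ₀ = 0, λ₀ = 0.8, α₀ = 1.3, β₀ = 0.015) plus Gaussian motor noise
(sd 0.02), seven synthetic subjects per group — matching the study-scale
group sizes.  This emulates the *structure* of real data (initial flat
prior, fast mean learning, slow variance learning, motor jitter) but not
its idiosyncrasies: no lapses, no drifting motor bias, no between-subject
parameter spread, no deviation from the Gaussian-linear response family.
Tests passing on these cohorts therefore validate the machinery —
generative calibration, estimator recovery, exact inference, model
ordering — not claims about human behaviour.

## Adaptation-speed statistics

Learning-curve comparisons use two statistics over binned gains:

* **bins-to-criterion**: first bin with |r − r_true| < 0.1 (censored at
  n_bins + 1 when never reached);
* **bins-to-midpoint**: first bin crossing halfway from the segment's own
  starting gain toward the new true gain.

The midpoint form is used wherever two segments start at different
distances from the target gain (comparing post-switch adaptation against
learning from scratch, and the up- versus down-switch asymmetry): it is
invariant to the starting gap, so a constant-rate filter scores the same
in both segments while the conjugate accumulator — whose effective step
size shrinks as 1/n — scores dramatically slower after trial 250.  The
absolute criterion is kept for convergence checks against a known optimum.
With ~250 trials of accumulated evidence (λ ≈ 250), the conjugate model's
variance estimate moves at O(1/n) and typically cannot re-converge within
the remaining 250 trials in either switch direction; the midpoint statistic
still resolves the up/down asymmetry (crossing within ~7 bins after a
variance increase versus censoring after a decrease), which is why it is
the statistic of record for that comparison.

## Problem sizes

Defaults chosen for the shipped tests and scripts: 200 simulated runs per
objective evaluation during fitting and 200 seeded replications for the
protocol-2 signatures (Monte-Carlo SEs comfortably below the effect sizes
involved); 1000+ switches (≈ 25 sessions) for the switch-detection curve;
a 400×400 lattice for the grid-integration oracle; 8-trial sessions for
exhaustive enumeration (256 admissible sequences).  All are parameters, not
constants, and scale up without code changes.

## Known limitations

* The NIG learner's μ and σ² point estimates are plugged into the linear
  rule; the exact posterior-predictive placement differs by small
  Jensen-gap terms early in a session (the predictive variance mode bounds
  the effect).
* The change-point observer assumes the generative hazard exactly; hazard
  misspecification (e.g. the constant-hazard flag) is available but not
  systematically explored.
* The linear filter's mean estimate is a package decision (running mean);
  any mean model that converges fast leaves its variance dynamics — the
  quantity under study — unchanged.
* Parameter *values* of the NIG init are only weakly identified from
  binned curves (different inits can produce near-identical gain
  trajectories); recovery is therefore asserted on the implied gain
  trajectory (RMS ≤ 0.05), not on the raw hyperparameters.
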