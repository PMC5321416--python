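# Methods

This note documents the model, the estimation machinery, the synthetic-data
generator that stands in for raw trial data, and the design choices made
where the design was genuinely open.

## Observer model

Perceived pain is the Gaussian fusion of a condition-specific prior
`N(μ_prior, σ_prior)` with sensory evidence `N(μ_s(weight), σ_s)`, where
`μ_s(weight) = a·ln(weight) + b` is an affine function of log stimulus
force.  The posterior is Gaussian with precision `1/σ_prior² + 1/σ_s²`
and precision-weighted mean; the posterior mean is the point prediction
of the reported rating.  Natural logarithms are used throughout — any
other base is absorbed into `(a, b)` and fixing one makes coefficients
reproducible.  The posterior is *not* truncated at zero: ratings are
magnitude estimates relative to the 512 mN reference (reference ≡ 100),
bounded below but effectively far from zero in every regime of interest,
and the plain-Gaussian algebra is kept exact.  Truncation is an extension
hook, not a default.

The default psychophysical map is anchored through two points — sensation
7.5 at 64 mN and 57.5 at 256 mN, the mean conditioning-session ratings at
the two conditioning intensities — giving slope `a = 50/ln 4 ≈ 36.07`
(each doubling of force adds exactly 25 rating points) and
`μ_s(512) = 82.5`.  `calibrate_map` fits per-participant or pooled maps
by OLS of rating on ln(weight) when data are available; maps are
per-participant in principle (individual scaling differs), pooled or
fixed in practice when the design cannot identify them.

### Observation model

Nothing in the posterior algebra dictates how an *observed* rating is
distributed.  The package takes each conditioning-trial rating to be
drawn from the posterior itself, `r ~ N(μ_post(weight), σ_post)` — the
posterior read as a response distribution.  This is the only distribution
the fusion provides, and it is stated prominently because everything
downstream (the likelihood inside the MCMC, the generator, the
credible-interval calibration) inherits it.

## Prior estimation by MCMC

Free parameters per participant are `(μ_prior, σ_prior)` for each choice
condition plus a sensory noise `σ_s` shared across the two conditions
(a single sensory channel; a per-condition option exists).  Weakly
informative hyperpriors on the 0–100 rating scale:

| parameter | hyperprior | rationale |
| --- | --- | --- |
| μ_prior | Normal(50, 50) | covers the scale without pinning it |
| σ_prior | HalfNormal(30) | allows flat-ish through very tight priors |
| σ_s | HalfNormal(30), or fixed | see below |

The sampler is component-wise random-walk Metropolis: each iteration
sweeps the parameter block one coordinate at a time, with σ coordinates
proposed on the log scale (multiplicative steps, Jacobian-corrected).
Full-block natural-scale proposals mix poorly on the curved
σ_prior–σ_s ridge; log-scale coordinate sweeps converge reliably.
Per-chain, per-coordinate step sizes adapt toward ~40% acceptance during
burn-in only, so the retained draws form a valid Markov chain.  Defaults:
4 chains × 5,000 iterations, 1,000 burn-in, overdispersed data-informed
starts.  Convergence is summarised by split-R̂ (warning above 1.05;
`extract_observer` refuses non-converged fits without an override) and,
for single fits, effective sample size via arviz.  Point estimates are
posterior means.  All participants and chains run as one vectorised
batch: participants are independent, so the batched chains are exact
per-participant chains, and a 24-participant study fits in a few seconds
on one CPU.

Correctness is anchored on a conjugate oracle: with both σ fixed, each
rating is linear-Gaussian in μ_prior and the posterior has a closed
normal-normal form; the sampler must match it within Monte-Carlo error.

### Fixed vs free sensory noise

Whether σ_s should be estimated or fixed from external psychophysical
calibration is genuinely open, and both modes are supported.  The
identifiability structure is asymmetric: doctor conditioning trials span
two stimulus levels, so the slope of rating on sensation identifies the
prior weight `w = σ_s²/(σ_s²+σ_prior²)`, but pharmacy trials sit at one
level and identify only `μ_post` and `σ_post`.  With ~16 doctor trials
the σ split is weakly identified, and its errors propagate into the
pharmacy prior mean as a `1/w` amplification, occasionally producing wild
estimates.  The *recovery experiment* therefore fixes σ_s at the
generator's population location by default — the same externally-anchored
status the map itself has — while pipeline fits of arbitrary datasets
keep the free-σ_s default.  Users running recovery with free σ_s can pass
`HyperPriors()` explicitly.

## Linear baseline and model scoring

The baseline regresses rating on the *same* estimated sensation
`μ_s(weight)` the observer uses, per participant, on conditioning trials,
then extrapolates to 512 mN.  Within the pharmacy condition every
conditioning trial delivers 256 mN, so the within-condition regression is
rank-deficient by design of the paradigm; the pharmacy baseline is
instead fit on the participant's full conditioning set (both choices),
the closest well-posed analogue.  The same fallback covers the rare
doctor schedule whose trials all land on one level, and a schedule with
a single level overall collapses to the intercept-only mean predictor.

Models are scored on test-session prediction residuals pooled over
participants within a condition:

    RMSE = sqrt(SSE/n),    BIC = n·ln(SSE/n) + k·ln(n)

with k = 3 for both models (μ_prior, σ_prior, σ_s vs slope, intercept,
residual sd).  Applying the Gaussian-error BIC to held-out error rather
than training likelihood is unusual but deliberate: both models train on
conditioning data only, so test-session error is a genuine out-of-sample
comparison, and equal k makes the BIC ordering the SSE ordering.  A
per-participant RMSE decomposition is emitted alongside the pooled
headline numbers.

## Behavioral statistics

Choice probabilities per trial index and overall; per participant ×
session × condition means and sample SDs (n−1 denominator); paired
t-tests across participants (df = n−1, two-sided, α = 0.05, no
multiple-testing correction); an OLS trend test of doctor-choice
proportion on trial index; Pearson correlation of per-participant
predicted vs actual test means.  Aggregation is always participant-level
before testing, so a 24-participant study yields df = 23.

## Synthetic-data generator

The generator emulates the paradigm exactly: 40 conditioning trials per
participant with exogenous Bernoulli(0.403) doctor choices (the observed
doctor rate; no decision process is modelled — choices in the paradigm
reflect a cost/relief trade-off outside the observer model), doctor
trials at 64/256 mN equiprobably, pharmacy at 256 mN, and a test session
of 15 trials per condition (doctor / pharmacy / control — the source
design does not state the test-session trial count, so it is
configuration) at 512 mN.  Ratings follow the observation model above
plus optional independent report noise, floored at 0 and uncapped above.
Participants draw `μ_prior` per condition from a population with a shared
participant-level offset (overall pain sensitivity) plus condition
idiosyncrasy, `σ_prior` and `σ_s` from truncated normals.

Two named configurations:

* **neutral** (default; used for parameter recovery): condition prior
  means 45/60/90 (doctor/pharmacy/control) with 14-point spread, tight
  priors (σ_prior ≈ 5) against σ_s ≈ 15, zero report noise.  Tight
  priors give a prior weight near 0.9, so prior means are strongly
  expressed in the data — the regime in which recovery of the estimation
  target is identifiable — and zero report noise makes the generative
  process exactly the fitted model, the standard design for a
  parameter-recovery study.  Recovery scoring: bias, RMSE,
  correlation(true, estimated) per parameter and condition, and 95%
  credible-interval coverage of true prior means.
* **paper-like** (used for the qualitative-pattern and model-comparison
  studies): prior means 84.6/87.6/92.8 anchored to the published
  test-session group means, broad doctor prior (σ_prior ≈ 24) vs tight
  pharmacy/control priors (≈ 12), σ_s ≈ 15, participant offset SD 10,
  report noise 5.  The broad doctor prior reproduces the paradigm's
  precision asymmetry; combined with the 64/256 stimulus mixture it makes
  doctor-trial conditioning SDs exceed pharmacy SDs in ≈99% of simulated
  participants.  Neither configuration claims to be the latent truth
  behind the original data.

A third regime, `simulate_linear_study`, generates ratings from a pure
linear response with *per-participant* slopes N(1, 0.15) and intercepts
N(0, 8) and no prior influence.  Heterogeneous scaling matters: a
homogeneous slope-1/intercept-0 response coincides exactly with the
observer's fixed sensory channel, making the Bayesian model correctly
specified even in the "linear" regime and the inversion check vacuous.
With individual scaling — the realistic reading of a linear response, and
the reason the psychophysical map carries a participant subscript — the
fixed-map observer is misspecified and the adaptive linear baseline wins,
as it should.

### What passing tests do and do not show

The generator shares the fitted model's Gaussian response form, static
(non-learning) priors, and exogenous choices.  Real data bring scale
compression near the rating ceiling, sequential learning across the 40
trials (deliberately out of scope, matching the static model), choice
autocorrelation, and drifting attention — none of which the generator
emulates.  Passing recovery and pattern checks therefore validate the
*machinery* (estimator correctness, statistical pipeline, comparison
logic) under the model's own assumptions, not the model's adequacy for
real participants.

## Problem sizes and numerical choices

Replicate studies use 24 participants × 40 conditioning trials — the
study's own scale; pattern detection runs 50 replicates, model comparison
50 (Bayes regime) and 20 (linear regime) with a lighter 2-chain × 2,000
sampler per fit, which is sufficient for point predictions.  Paradigm
fidelity checks use 10,000 conditioning trials.  Grid integration for the
fusion oracle uses 20,001 points over ±8σ.  Ties in BIC are reported as
no winner.  Degenerate inputs raise typed errors (rank-deficient designs,
zero-variance test statistics, SSE = 0 in the BIC, both-flat fusion)
rather than returning NaN.

## Known limitations

* The doctor condition's broad prior carries little per-participant
  signal at n = 24; single-study predicted-vs-actual correlations for the
  doctor condition are accordingly weak and noisy (the high-precision
  pharmacy condition correlates well) — the same reliability asymmetry
  the original comparison reported.
* σ_s recovery is poor when free (correlation with truth near zero at
  40 trials); only the prior parameters are recoverable at this scale.
* No trial-by-trial prior updating, no utility-based choice model, no
  hierarchical pooling across participants: the model is static and
  per-individual by design.
* Control-condition priors cannot be estimated (no conditioning data
  exist for control); the control observer uses a configurable prior,
  flat by default, and control predictions are reported only where one is
  supplied.
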