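# Methods

`bisectlab` implements the complete computational chain of a temporal
bisection experiment: designing a first-order counterbalanced session,
generating behavior from a two-stage drift-diffusion account of interval
timing, recovering psychometric and decision-model parameters, measuring
trial-history (carryover) effects, and performing time-frequency EEG
statistics with cluster-based permutation correction. Everything runs on
synthetic data produced by the package itself, so every stage is testable
without external recordings.

## Task and design

The bisection task presents one of seven durations, logarithmically
spaced between 300 and 900 ms, and asks for a "short"/"long"
classification relative to an implicit standard. The geometric mean of a
log-spaced set equals sqrt(t_min * t_max) — 520 ms for the canonical set —
and serves as the natural categorical boundary.

Trial order is first-order counterbalanced: over the alphabet of seven
duration labels plus a NULL (no-stimulus) label, every ordered label pair
occurs equally often. Such an order is exactly an Eulerian circuit on the
complete transition multigraph with `reps` parallel edges per ordered
pair; we realize it with Hierholzer's algorithm using seeded random edge
choice. Any uniform-count circuit has the property the analyses need
(equal transition counts), so no attempt is made to reproduce any
particular published generator's path weighting. The circuit is cyclic;
it is reported linearly by cutting at a random position, and transition
counts are accounted cyclically. With 8 repetitions per transition this
yields 512 trials in total, 448 stimulus trials, 64 presentations per
label, and 64 ordered trial types. Trials that follow a NULL carry no
prior-duration annotation and are excluded from carryover conditioning —
that is what the NULL label is for. An optional lead-in of standard
presentations at the geometric mean can be prefixed outside the
counterbalanced count; it is excluded from analysis.

## Generative model

**Stage one (temporal accumulator).** During a stimulus of duration T an
accumulator follows dx = A dt + m sqrt(A) dB. The endpoint x(T) is
Gaussian with mean A·T and variance m²·A·T, reproducing scalar timing:
longer intervals are measured more variably. The accumulation rate is
normalized to the criterion duration, A = 1/0.52 s⁻¹, so the expected
endpoint is exactly 1 at the categorical boundary. A delta-rule update of
A (`learning_rate`) is exposed but off by default, because no specific
learning rule is required for the analyses here. The noise coefficient
defaults to m = 0.2, i.e. a ~20% coefficient of variation at the
standard — a typical human temporal Weber fraction.

**Stage two (decision diffusion).** At stimulus offset a Wiener
diffusion with unit diffusion coefficient races between a lower ("short")
and upper ("long") boundary separated by `a`, from relative start `z`,
with drift `v` and non-decision time `t0`. The stage-one endpoint drives
the decision stage in two ways:

- starting point: z = clip(0.5 + kappa·(x − 1), 0.05, 0.95), the minimal
  monotone (affine, clipped) map; kappa defaults to 0.35;
- drift: v = v_scale·(x − A·b), where b is the current categorical
  boundary; the drift is therefore signed by which side of the boundary
  the accumulated evidence landed on (v_scale defaults to 4 s⁻¹).

Two further duration dependences implement the theory's predictions for
the decision stage and give the recovery tests something real to
recover: boundary separation rises with the expected distance from the
criterion, a(d) = a_base + a_mod·|A·d − 1| (so `a` dips for mid-range
durations), and non-decision time falls linearly with duration,
t0(d) = t0_base + t0_slope·(d − 0.52) with t0_slope = −0.1 by default.
Defaults (a_base = 1.1, t0_base = 0.25 s) were chosen so a simulated
session looks like published bisection behavior: BP near the geometric
mean, CV ≈ 0.2, mean RTs between 0.35 and 0.55 s with slower responses
near the boundary, and ~5% of trials outside the 100–1000 ms band.

**Carryover.** The categorical boundary leaks toward the previous
trial's duration: b ← (1−g)·b + g·d_prev with g = `carryover_gain` ∈
[0, 1]. This yields the classic positive regression of the bisection
point on the prior duration. We implement carryover as boundary drift
(not stage-one rate drift) since the effect to emulate is a shift of the
classification criterion. Decision paths are simulated by
Euler–Maruyama with dt = 1 ms plus a Brownian-bridge within-step
crossing correction, which removes the leading-order discretization bias
of the naive scheme (verified against closed-form absorption
probabilities at 10⁵ paths).

## Psychometrics

Choice proportions per duration are fit by a cumulative Gumbel on log
duration, F(d) = 1 − exp(−exp((log d − α)/β)) — on the log axis a
binomial GLM with complementary log-log link. The fit is maximum
likelihood (no priors, lapse rates fixed at 0 by default), implemented as
a batched Fisher-scoring Newton solver so that bootstrap resamples and
sliding windows fit thousands of curves in one vectorized pass; it is
cross-checked against `statsmodels` GLM in the test suite. A linear-axis
variant is available behind a flag. From the fit: BP = F⁻¹(0.5),
DL = (θ75 − θ25)/2, CV = DL/BP. Fits with no measurable crossing
(all-identical responses, or slope indistinguishable from flat) are
flagged non-converged with missing thresholds; complete separation (step
data) is handled by capping the slope, leaving the thresholds bracketed
by the adjacent levels.

Threshold uncertainty uses a parametric bootstrap (binomial resampling
from the fitted curve, 1999 resamples by default) with bias-corrected
(BC, not BCa) percentile intervals. A delta-method SE of the BP from the
Fisher information is also computed; it powers the weighted carryover
regression below. RT filtering keeps 100 ms ≤ RT ≤ 1000 ms with
inclusive bounds (the conservative reading of "between") and logs the
removal count.

## Carryover and sliding-window analyses

Perceptual carryover: one psychometric fit per prior-duration bin
(trials after NULL excluded), then a regression of BP on prior duration.
Because each bin's BP has a known sampling variance (delta method), the
slope is estimated by variance-weighted least squares with a z interval
— markedly better calibrated and more powerful than an unweighted 7-point
residual-t regression. Bins are the seven prior durations, not
quantiles; a bin is dropped when any present-duration level has fewer
than 4 trials (a counterbalanced session supplies exactly `reps` = 8
trials per ordered pair, so demanding the full 8 after RT filtering
would discard nearly every bin). Decisional carryover is the BP
difference between trials following a "short" versus a "long" response.

The sliding-window series fits every window of `window` consecutive
trials (default 131, a config value — the minimum window length is
sequence-instance dependent) in one batched pass, advancing one trial at
a time, with a centered 10-point moving average (edge-truncated) for
display. Windows in which any duration level has fewer than 8 trials are
flagged rather than silently trusted. `minimum_window()` computes, for a
realized sequence, the smallest window length such that every contiguous
window contains at least `min_per_level` trials of every duration
(verified against a brute-force scan of all windows); it operates on the
stimulus trials only, since analysis windows slide over choice data.

## Decision-model estimation

The Wiener first-passage density is evaluated by the standard
small-time (reflected images) and large-time (sine series) expansions,
choosing per call whichever needs fewer terms for the requested
truncation error; the upper-boundary density follows by reflection. The
module's core oracles — normalization to 1, closed-form absorption
masses, and χ² agreement with simulated path histograms — are exercised
over a 20-point parameter grid. Starting-point variability `sz`
(uniform) is integrated by 11-point Gauss–Legendre quadrature, validated
against dense averaging. Only the decision stage is ever fit; stage-one
parameters exist solely in the generator.

Hierarchical Bayesian estimation draws subject-level parameters from
truncated-normal group distributions with weakly informative priors
(group means: normal with generous scales; group SDs: half-normal). Any
of a, v, t0, z (and optionally sz) can vary by duration, phase
(baseline/stimulation), or session. Sampling is adaptive random-walk
Metropolis-within-Gibbs: subject-level updates evaluate only the trials
of the affected cell; group-level means and log-scales get separate
adaptively tuned updates (target acceptance 0.44, adaptation during
burn-in only, so the post-burn chain is a valid fixed-kernel sampler).
Chains start overdispersed; defaults are 4 chains × 5000 samples with
2000 burn-in. A per-cell constraint keeps t0 below the fastest RT *of
that cell* — bounding duration-indexed t0 by the subject's global
fastest RT provably flattens the recovered t0-by-duration profile.

Convergence is diagnosed by a between/within-chain variance-ratio
statistic, R = sqrt(1 + (B/n)/W): exactly 1 for identical chains,
monotone in chain-mean disagreement, and below 1.01 for long independent
stationary chains. Fits with any R > 1.1 are returned flagged. Model
comparison uses DIC = D̄ + p_D with p_D = D̄ − D(θ̄) evaluated at
posterior-mean subject parameters. Posterior predictive checks simulate
500 datasets (default) at posterior-mean parameters and compare observed
per-duration choice proportions and RT quantiles with the simulated
2.5–97.5% envelope. A per-subject maximum-likelihood (Nelder–Mead)
fallback is provided for non-hierarchical fits.

When the full generative chain is fit with duration-indexed parameters,
the recovered profiles reproduce the implanted decision-stage patterns:
drift negative below and positive above the boundary and increasing with
duration; non-decision time decreasing; boundary separation dipping near
the criterion; starting point rising with duration (with its variability
growing as sqrt(T) from stage-one noise).

## EEG time-frequency statistics

The synthetic epochs are unit-variance 1/f-shaped Gaussian noise
(amplitude spectrum f^(−χ/2), χ = 1 by default) plus a Hann-windowed
oscillatory burst at the center of the effect band (17–23 Hz by default,
window 0.3–0.9 s post-onset), with a Gaussian channel topography. The
single-trial oscillation power is snr·(1 + slope·(r − r̄)) clipped at
zero, where r is the present- or prior-trial duration, so a per-pixel
regression of power on r recovers the implanted slope. The generator
emulates band-limited power effects on stationary background noise only
— no evoked potentials, no channel covariance structure, no artifacts —
so passing tests demonstrate the statistics pipeline's calibration and
sensitivity, not robustness to real-world preprocessing problems.

Morlet decomposition uses 100 log-spaced frequencies from 10 to 40 Hz
(tests and the acceptance script use 40 for speed) with the
EEGLAB-style `[3, 0.5]` cycle schedule: cycles(f) = c0 + s·(c0·f/f0 −
c0), i.e. the wavelet widens half as fast as frequency rises. Samples
whose wavelet half-support (cycles/(2f)) extends beyond the epoch are
flagged invalid rather than trimmed; bit-exact replication of any
particular toolbox's padding is not attempted. Baseline handling is a
per-trial division by that trial's mean power in −200–0 ms per frequency
(robust to single noisy trials, unlike average-then-divide; both are
compared in a test with an implanted outlier trial), or no baseline —
a config switch, since both conventions are in common use.

Cluster inference thresholds pixelwise one-sample t statistics
two-tailed at p = 0.05, forms 8-connected clusters in the
frequency × time plane (single-channel analysis, so no channel
adjacency), pools positive and negative clusters into one
maximum-cluster-size null built by per-subject sign flipping (2000
permutations by default, seeded), and assigns add-one-corrected
p-values. Cluster mass is available as an alternative statistic. Paired
condition contrasts pass per-subject difference maps through the same
machinery (sign-flipping differences is equivalent to swapping condition
labels). Family-wise error on null maps is verified to sit inside the
binomial 99% interval of the nominal 5%.

## Reproducibility and problem sizes

Every stochastic stage derives its seed deterministically from one
global seed plus the stage name; identical configurations produce
byte-identical outputs and manifests. The test suite and acceptance
script use reduced problem sizes chosen to keep a full run on one CPU
comfortable while leaving the measured quantities well inside their
tolerances: hierarchical recovery at 19 subjects × 448 trials (4 chains
× 2000 samples), condition attribution over 20 replicate 6-subject
experiments, psychometric calibration over 200 datasets with 499
bootstrap resamples, carryover calibration over 100 sessions, and EEG
calibration at 100 null runs × 500 permutations plus 50 implant-recovery
runs at 40 frequencies.

## Known limitations

- The hierarchical sampler is a straightforward adaptive Metropolis
  scheme; it is reproducible and correct but mixes more slowly than
  gradient-based samplers for strongly correlated posteriors.
- Inter-trial drift variability (sv) and non-decision-time variability
  (st) are not modeled.
- The Gumbel fit exposes 25/50/75% quantile semantics only; no
  particular toolbox's threshold conventions are reproduced.
- Group-level inference across real subjects (ANOVAs, signed-rank
  tests) is out of scope: the pipeline exports per-subject summary
  tables for external statistics packages.
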