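# bisectlab

Toolkit for temporal-bisection psychophysics: counterbalanced session
design, a two-stage drift-diffusion generator of choice/RT data,
psychometric (cumulative Gumbel) fitting with bootstrap thresholds,
trial-history (carryover) and sliding-window analyses, hierarchical
Bayesian drift-diffusion estimation, and Morlet time-frequency EEG
statistics with cluster-based permutation correction.

It is aimed at researchers who study interval timing with bisection-type
tasks and want a tested, seed-reproducible pipeline from design to
statistics — including fully synthetic data generation, so every stage
can be validated without any recordings.

## The model in brief

In the bisection task a stimulus of duration *d* (seven log-spaced values
between 300 and 900 ms; geometric mean √(0.3·0.9) = 520 ms) must be
classified "short" or "long". The generative account is a two-stage
diffusion:

1. a temporal accumulator dx = A·dt + m·√A·dB integrates during the
   stimulus; with A normalized to the criterion duration its endpoint
   x(T) ~ N(A·T, m²·A·T) is 1 at the boundary (scalar timing);
2. at offset, a Wiener decision process with boundary separation *a*,
   drift *v*, starting point *z* and non-decision time *t₀* races
   between "short" (0) and "long" (*a*); the stage-one endpoint sets
   *z* and, relative to the categorical boundary, the sign of *v*.

The categorical boundary can leak toward the previous trial's duration,
producing the carryover effect: the bisection point BP = F⁻¹(0.5) of the
psychometric function F(d) = 1 − exp(−exp((log d − α)/β)) shifts with
the prior duration. Estimation inverts the decision stage with the
Wiener first-passage-time likelihood under hierarchical Bayes
(Metropolis-within-Gibbs, Gelman–Rubin diagnostics, DIC model
comparison, posterior predictive checks). EEG analysis regresses Morlet
wavelet power (10–40 Hz, EEGLAB-style [3, 0.5] cycle schedule) on trial
durations per time-frequency pixel and controls family-wise error with
a maximum-cluster-size permutation statistic.

See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from bisectlab import design, synth, psycho, sequential

stimuli = design.make_stimulus_set(0.3, 0.9, 7)
seq = design.generate_sequence(7, 8, include_null=True, seed=1)
table = design.annotate_transitions(seq, stimuli)
print(len(seq), seq.n_stimulus_trials, round(stimuli.geometric_mean, 3))
# 512 448 0.52

spec = synth.default_generative_spec(seed=3)
trials = psycho.filter_rt(synth.simulate_bisection_dataset(table, spec))
fit = psycho.fit_gumbel_trials(trials)
print(round(fit.bp, 4), round(fit.dl, 4), round(fit.cv, 4))
# 0.5323 0.1129 0.2122
```

The sequence has 512 trials (448 stimulus + 64 null), every ordered
label transition occurring exactly 8 times. The simulated session's
bisection point (0.532 s) lands near the 520 ms geometric mean, with a
difference limen of 113 ms and a coefficient of variation of 0.21 —
typical human-scale precision. Adding `carryover_gain=0.3` to the
generator and running `sequential.carryover_bp(trials)` yields a
significantly positive regression slope of BP on the prior trial's
duration, the perceptual carryover signature.

The same flow is available from the shell:

```bash
bisectlab design --reps 8 --seed 1 --out trials.csv
bisectlab simulate behavior --design trials.csv --seed 3 --out sim.csv
bisectlab psychometrics --in sim.csv --boot 1999 --seed 0 --out fits.json
bisectlab run --seed 11 --out results/demo
```

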