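# Methods notes

## The observer model and its assumptions

Responses are modelled as a linear template matcher with late additive
Gaussian noise. On a trial with shift profiles *s₁, s₂* (cents), unit-norm
template **u** and stimulus-noise SD σ_ext, the decision variable is
`e = u·(s₁ − s₂)/σ_ext`; the observer answers "interval 1" iff
`e + z > c` with `z ~ N(0, σ²)`. Ties (`e + z = c`, a measure-zero event)
resolve to interval 2. The model has no lapse rate, no learning and no
sequential dependencies; internal noise is drawn fresh on every presentation,
including the repeated double-pass trials — that independence is what makes
response consistency informative about σ.

**Units contract.** σ and *c* live at the decision stage, in units of the
stimulus-noise SD as seen through the unit-norm template. For untruncated
stimulus noise each projection `u·s/σ_ext` is exactly standard normal
(any unit **u**), so the evidence is `N(0, 2)`. The noise estimator assumes
this same convention; the two modules must never diverge on it.

## Stimulus noise and clipping

Per-segment shifts are `N(0, 70² cents)` bounded at ±2.2 SD. The bound is
enforced by **rejection resampling** by default (a truncated Gaussian with a
smooth density); hard clipping is available as `clip_mode="hard"` (point mass
at the bounds). The two differ in their moments: the truncated SD ratio is
`sd(truncnorm(−2.2, 2.2)) ≈ 0.916`, the hard-clipped ratio ≈ 0.975.

Truncation matters downstream: with the default clipping the evidence
variance is `2 × 0.8394 ≈ 1.68` rather than 2, i.e. the effective external
noise is ~8% smaller than nominal. Because the noise estimator fixes the
idealized evidence at `N(0, √2)` (see below), estimates from fully simulated
clipped-stimulus sessions carry a ~9% upward scale bias (σ̂ ≈ 1.09 σ). At
σ = 1 this is well inside sampling error at realistic repeat counts; at σ = 3
it approaches +0.3. Parameter-recovery benchmarks therefore generate their
double-pass summaries from the same idealized model the estimator inverts,
which isolates sampling noise and grid resolution; the full-observer route is
checked separately at σ = 1 where the attenuation is negligible relative to
the tolerance.

## Double-pass inversion: numerical choices

- **Evidence distribution.** The idealized double-pass observer uses
  `e ~ N(0, √2)` fixed within a trial with two independent `N(0, σ)` draws.
  The literature on double-pass consistency requires *some* fixed convention
  here; this one is the unique choice consistent with the units contract for
  a linear observer.
- **Forward model.** Monte Carlo with 10⁵ trials per grid point by default,
  using **common random numbers**: one set of evidence/noise draws shared by
  the entire grid. That makes the error surface smooth, the predicted
  consistency non-increasing in σ and the predicted bias exactly
  non-increasing in *c*, and lets the whole (101 × 121) table be built once
  (~0.5 s) and reused across participants. The table is seed-stamped.
- **Search.** Exhaustive grid, σ ∈ [0, 5] step 0.05, c ∈ [−3, 3] step 0.05,
  minimising the unweighted squared error on the (consistency, bias) pair.
  Both parameters are searched jointly — bias is part of the fitting target,
  not fixed from the observed first-option rate. Ties break toward smaller σ,
  then smaller |c|.
- **Censoring.** Double-pass data cannot distinguish very large σ values from
  each other (consistency saturates near 0.5), so estimates ≥ 4.8 (configurable)
  are flagged censored; they mean "at least this noisy". Estimates always lie
  in [0, 5] by construction.
- The estimator is agnostic to the repeat count; 25- and 50-repeat session
  variants feed the same inversion, with `n_repeats` carried in the summary
  so analyses can stratify by design.

## Classification images

- Kernels are chosen-minus-unchosen mean profiles, RMS-normalised. A kernel
  whose RMS is below 10⁻⁹ cents raises an explicit degenerate-kernel error
  rather than dividing silently (random responders at small n can get there).
- For a linear observer the expected kernel is proportional to the template;
  internal noise attenuates its amplitude but not its direction, so the
  normalised kernel is a consistent direction estimate. Per-segment clipping
  makes the stimulus distribution very mildly non-spherical; the induced
  directional distortion is below 0.01 in cosine at 10⁵ trials for the
  final-rise template.
- **Typicality** is the raw MSE between normalised kernels: 0 for identical,
  4 for exactly inverted. No sign flip or similarity relabeling is applied;
  analysts choose the sign convention for regressions themselves. Controls
  are scored against the **leave-one-out** average of their own group (full
  average would inflate their own typicality); other groups are scored
  against the full control average.
- Long sessions are truncated to the first 150 trials before kernel
  estimation when matching participants measured at 150 trials, so estimator
  variance is comparable.

## Cohort statistics

- Mann–Whitney: exact null when min(n) ≤ 8 and the pooled sample is tie-free,
  otherwise the midrank normal approximation with tie correction. The
  reported U counts (x > y) pairs, so complete separation with larger y gives
  U = 0; the exact two-sided p doubles the smaller tail, matching brute-force
  permutation enumeration bit for bit.
- Regressions: plain OLS (homoskedastic errors assumed; no robust covariance,
  which inflates false positives at cohort-sized n), with case-resampling
  percentile bootstrap CIs on the slope (default 10⁴ resamples). Percentile
  intervals undercover slightly at n ≈ 22 (measured ≈ 92% for a nominal 95%);
  BCa would be the natural extension but is not implemented. Degenerate
  resamples with zero predictor spread are redrawn.

## What the synthetic generator does and does not emulate

The generator reproduces the experiment's statistical structure: per-segment
Gaussian pitch perturbations with clipping, 150-pair sequences in 3 blocks of
50 with a verbatim repeated block (25- or 50-repeat variants), and
template+noise responders with group-level noise distributions
(control 0.7 ± 0.37, patient 2.54 ± 1.90 stimulus-noise units, truncated at
zero). It does **not** emulate: real listeners' deviations from linearity,
lapses, fatigue or serial dependence; heterogeneous templates within a group
(all simulated observers share the final-rise template, so group differences
in typicality arise only from kernel estimation noise, not from genuinely
atypical representations); audio rendering or presentation timing. Passing
tests therefore validate the estimation machinery under the stated model, not
the model's adequacy for any particular listener.

Because small-sample double-pass consistency is noisy and the consistency→σ
mapping is convex, measured group means sit somewhat above the generating
values (e.g. ≈ 0.83 for the 0.7 group at 50 repeats); this is a property of
the estimator under the study's repeat counts, shared by any double-pass
inversion, and is why recovery claims are made against the idealized
generator at 3000 repeats.

## Problem sizes

Defaults used by the test suite and the acceptance script: 10⁵ Monte-Carlo
trials per lookup grid point; 10⁶ samples for forward-model/closed-form
agreement; kernel recovery at 150/10³/10⁴ trials; noise recovery at 3000
repeats × 20 replicates per σ level; group separation over 200 replicates of
the full 43-participant pipeline. These sizes give Monte-Carlo error well
below every stated tolerance.
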