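# doublepass

A toolkit for **reverse-correlation psychophysics of speech prosody** with a
*representation + noise* observer model. It is aimed at researchers and
clinicians who want to characterise how an individual listener perceives
prosodic pitch contours — for example interrogative intonation after a
right-hemisphere stroke — using two interpretable parameters per participant:

1. an **internal representation** (classification image): the pitch-contour
   template the listener compares stimuli against, and
2. an **internal noise** level: the SD of the Gaussian variability with which
   that template is applied from trial to trial, in units of the stimulus
   (external) noise SD.

## The method

**Stimuli.** A short utterance is divided into `n` segments (default 6 × 71 ms)
and each segment's pitch is shifted independently by
`ε_k ~ N(0, 70² cents)`, bounded at ±2.2 SD. Listeners hear pairs of such
manipulated utterances (2AFC) and choose the one that sounds most
interrogative. The sequence of 150 pairs is a **double-pass** design: one block
of pairs is repeated verbatim later in the session, without the listener's
knowledge.

**Observer model.** Responses are modelled by a linear template matcher with
late additive noise. With unit-norm template **u**, profiles *s₁, s₂* (cents)
and stimulus-noise SD σ_ext, the decision variable is

    e = u · (s₁ − s₂) / σ_ext ,   respond "interval 1" iff e + z > c,   z ~ N(0, σ²)

σ is the internal noise and *c* the criterion (response bias).

**Classification images.** The representation is estimated as the mean shift
profile of chosen stimuli minus the mean profile of unchosen stimuli,
RMS-normalised. **Representation typicality** is the mean squared error
between a listener's normalised kernel and the (leave-one-out) control-group
average — 0 for an identical representation, 4 for an exactly inverted one.

**Internal noise.** From the repeated trials we observe *response consistency*
(probability of answering a repeated pair identically) and *response bias*
(probability of choosing interval 1). A Monte-Carlo forward model of the
idealized double-pass observer (evidence `e ~ N(0, √2)` fixed within a trial,
two independent noise draws) predicts both quantities for any (σ, c);
exhaustive search over σ ∈ [0, 5] × c ∈ [−3, 3] returns the pair minimising
the squared error against the observed values. Estimates at the top of the
range (≥ 4.8 by default) are flagged **censored**: double-pass data cannot
distinguish them from anything larger.

**Cohort statistics.** Group comparisons use the Mann–Whitney rank-sum test
(exact null for small groups); covariate regressions use OLS with
case-resampling percentile bootstrap confidence intervals.

## Worked example

The `demo` subcommand simulates a full two-group study — 21 low-noise
"control" observers (σ ~ N(0.7, 0.37²) truncated at 0) and 22 high-noise
"patient" observers (σ ~ N(2.54, 1.90²)), all sharing a final-rise template,
each running a 150-trial double-pass session — then estimates both parameters
per participant and compares the groups:

```
$ doublepass demo --seed 1 --out-dir demo_out
     sigma control-patient: diff=-2.528 U=32.5 p=1.336e-06 CI=[-3.240, -1.782]
typicality control-patient: diff=-0.119 U=102.0 p=0.001796 CI=[-0.186, -0.059]
   control internal noise: M=0.83 (SD=0.57)
   patient internal noise: M=3.36 (SD=1.64)
```

Reading this output: the estimated internal noise of the simulated control
group (M = 0.83) sits close to its generating level, the patient group's is
both higher and more variable, and the Mann–Whitney test separates the groups
decisively on internal noise (U = 32.5, p ≈ 1e-6) and on representation
typicality (higher MSE in patients, p ≈ 0.002, driven purely by their noisier
kernels since both groups share the same true template). `demo_out/` contains
the per-participant estimates table, the normalised kernel matrices and the
comparison table as CSV.

The same pipeline is available programmatically:

```python
from doublepass import run_study
result = run_study(seed=1)
print(result.estimates.head())      # sigma, criterion, typicality per participant
print(result.comparisons)           # group-level rank-sum tests with bootstrap CIs
```

Other subcommands operate on files for real data: `generate` (stimulus
manifests and breakpoint files for a pitch-shifting tool), `simulate`
(observer trial logs), `kernel`, `noise` and `cohort-stats`. See
`examples/default_study.yaml` for the full configuration schema.

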