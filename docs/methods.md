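# Methods

This note documents the models, numerical choices and calibration behind the
package, and what the simulations can and cannot say about real listeners.

## Stimulus model

### Sinusoidal frame warping

The early region of the sentence is divided into `n = floor(region/frame)`
frames of 50 ms (configurable). Frame `i`'s duration ratio is

```
r_i = 1 + m · sin(2π · c · t_i + φ),    t_i = (i + ½)/n
```

with depth `m ∈ [0, 1]`, whole cycles `c` and phase `φ`. The modulator's
time variable is *normalised position within the warped region*, evaluated at
frame centres, so `c` cycles span the region exactly regardless of its
absolute length. Any remainder shorter than one frame is passed through
unwarped.

Exact duration conservation does not follow automatically: the discrete
frame-centre samples of a sine sum to zero only for special phases. We
therefore subtract the mean per-frame deviation from every frame (the
smallest uniform perturbation achieving exactness) and, if that correction
drives a frame negative (possible only near `m = 1`), clip it to zero and
redistribute the deficit over the remaining frames. The scheduled total
equals the original region duration to 1e-9 ms by construction; the audio
renderer keeps it to one sample by cumulative rounding of frame boundaries.

Waveform frames are resampled by linear interpolation onto a uniform grid of
the target length. This is deliberate: the perceptual quality of the warp is
irrelevant to the simulated experiment (the observer consumes timing, not
audio), and pitch-preserving time-scale modification is out of scope.

### Sentence template and trials

The sentence is represented as an abstract timeline — early carrier region,
gap region of reference duration `T` (1661 ms male / 1603 ms female
templates), final word. Early/final durations of the bundled templates
(1200/350 ms male, 1150/330 ms female) are plausible spoken-word lengths
chosen once; they only set the length of the warped region and of the
rendered audio, not any measured quantity. Stand-in audio renders words as
amplitude-modulated noise bursts. Within a trial, the same warp schedule
(same phase draw) is applied to the early region of the reference and of
both comparisons; speakers alternate strictly across trials.

## Adaptive procedure

2-down/1-up with multiplicative steps: the step is half the *current* level
until the track's second reversal and a quarter of the level thereafter,
always computed from the level before the move. This is the only reading of
"a fraction of the gap deviation" that keeps the early track inside [0, 1]
from its start at 1.0. Further conventions, fixed for reproducibility where
the procedure description is silent:

- A reversal is a change in the direction of movement; the recorded level is
  the pre-move level (the level at which the reversing response was
  collected). The move that *creates* the second reversal still uses the
  coarse step; later moves use the fine step.
- Levels clip to the bounds after stepping. A move entirely absorbed by a
  bound (level unchanged) is a repetition: it neither sets the movement
  direction nor can it create a reversal, so plateaus at a bound do not
  spuriously inflate the reversal count.
- Blocks whose track yields fewer than four reversals cannot support the
  last-four-reversal estimator; they are flagged invalid and excluded from
  the three-block mean. In the rare cell where *no* block yields four
  reversals (e.g. a track pinned at a bound by an extreme observer), the
  pipeline falls back to the mean final track level across blocks.

Two properties of this procedure are worth knowing when interpreting
simulated thresholds. First, multiplicative up/down steps are asymmetric on
the log scale, which biases the equilibrium slightly below the nominal
70.7% point; second, with only 20 trials per track the last four reversals
can include the initial descent from the high starting level, which biases
estimates upward. The net per-track biases, measured on a stationary
simulated observer, are about −7% (early track, start 1.0) and +7% (late
track, start 1.5) — inside the ±10% convergence band asserted by the tests,
but systematic. Real uses of this staircase inherit the same biases; the
late−early difference score absorbs a small procedure-induced offset
(~0.05) for a perfectly symmetric observer.

## Observer model

The paradigm's motivating theory — dynamic attending — says listeners
entrain to the sentence rhythm and focus attention at the expected
final-word onset. We formalise the *behavioural consequences* with the
minimal parametric observer that maps the three experimental factors onto
three parameters; it is a generative stand-in, not a mechanism claim.

Temporal-expectancy precision is a Gaussian SD `σ` expressed as a fraction
of `T`:

```
σ(condition, direction) = σ_base · penalty^[rhythm altered] · asym^[late onset]
d' = (ΔT/T) / σ
p(correct) = 0.5 + (0.5 − λ/2) · erf(d'/2)      (= (1−λ)·Φ(d'/√2) + λ/2)
```

so performance is at chance at zero deviation and saturates at `1 − λ/2`.
The analytic threshold of any cell at criterion level `p` inverts this link:
`ΔT/T = σ_cell · 2·erfinv((p − ½)/(½ − λ/2))` (`observer.threshold_at`),
with `p = √½ ≈ 0.707` for the 2-down/1-up rule.
Whether the early/late asymmetry in humans is
multiplicative on precision or additive on a decision criterion cannot be
decided from group thresholds alone; the model exposes only the single
multiplicative knob, a stated limitation.

### Defaults and calibration

Group defaults were set analytically so that expected cell thresholds
(`σ_cell` times the 70.7% factor) land near the reported group means of the
study this paradigm models (young early ≈ 0.30, late ≈ 0.53; unaltered
≈ 0.37 vs altered ≈ 0.45 pooled):

| parameter | young | older | role |
|---|---|---|---|
| σ_base | 0.34 | 0.47 | precision, best cell (unaltered, early) |
| rhythm penalty | 1.22 | 1.22 | σ inflation under rhythm alteration |
| asymmetry | 1.75 | 1.00 | σ_late/σ_early |
| lapse λ | 0.02 | 0.02 | attention lapses |

Between-subject variation is lognormal with unit mean (`exp(s·z − s²/2)`),
so group means stay at the calibrated values: `s = 0.35` on σ_base,
`0.08` on the penalty, and `0.25` (young) / `0.45` (older) on asymmetry.
The asymmetry spreads are derived from the reported paired effect sizes
(young d ≈ −1.46 with a 0.23 mean difference implies an SD of ~0.16; older
d ≈ −0.38 with ~0.07 implies ~0.18) and from the observation that the older
group splits into young-like and symmetric subgroups, which a wider
lognormal reproduces.

Battery covariates (GAP percent correct, S&C tapping slope, RD d′, WM
composite) are *simulated scores*, not simulated tasks: each is
`mean + sd·(c·z_latent + √(1−c²)·ε)` with coupling `c = 0.8`, where the
latent is the standardised log asymmetry for RD and the standardised log
σ_base for the other three. This reproduces the qualitative dissociation of
interest — RD correlates with the late−early difference score but not with
overall thresholds, while GAP/S&C/WM do the reverse. Scales are arbitrary
but plausible; the analysis stage only consumes correlations.

## Statistics

Paired *t* and Pearson *r* are delegated to scipy; Cohen's *d* is
`mean(diff)/sd(diff)` with the sample SD. The 2×3×2 split-plot ANOVA is
implemented in-package (no installed Python library covers a
between × within × within design): each within effect is projected onto an
orthonormal contrast basis (Kronecker products of normalised mean and
contrast vectors), a cell-means model over groups is fitted in contrast
space, and the univariate F is formed from traces of the hypothesis and
residual SSCP matrices. Group hypotheses are Type III (unweighted group
means), which matters for the default unequal group sizes (11 vs 10).
Greenhouse–Geisser ε = tr(S)²/(q·tr(S²)) is estimated from the pooled
within-group covariance in contrast space and applied to effects involving
the three-level rhythm factor; 1-df effects are uncorrected. For balanced
groups the decomposition satisfies the SS conservation identity exactly,
and the test suite verifies it against an independently coded textbook
mean-based split-plot oracle. Post-hoc tests are uncorrected for multiple
comparisons, matching the analysis practice this pipeline mirrors — stated,
not endorsed.

## Reproducibility

A single master seed drives everything. The cohort is drawn from
`SeedSequence(seed)`, and each subject runs on an independent child stream
`SeedSequence(seed, spawn_key=(subject_index,))`, so per-subject data are
reproducible regardless of execution order. Identical seeds produce
byte-identical output files (content-hashed in the run manifest).

## Problem sizes used by the tests

The convergence check uses 2000 interleaved blocks (the asymptotic track
biases are ±7%, so a few thousand blocks estimate the mean threshold to
well under 1% relative error); per-cell recovery averages 300 full-pipeline
replicates of a lapse-free observer; pattern reproduction uses 100 replicate
default cohorts. The full suite runs in well under a minute on one core.

## What passing tests do and do not show

The generator reproduces the *structure* of the paradigm's findings — the
rhythm-alteration cost, the young early-onset advantage, its absence in the
older profile, the RD dissociation — because those patterns are built into
the observer model and its calibration. Passing tests therefore validate
the pipeline (stimulus arithmetic, staircase bookkeeping, estimator and
statistics), not the theory: they show that *if* listeners behave like the
parametric observer, this procedure measures them faithfully. Real speech,
phonetic cues, training effects, non-stationary attention and criterion
shifts are all outside the model.

## Known limitations

- Linear-interpolation resampling is audibly crude; use a proper TSM
  algorithm if stimuli are for human ears.
- The observer's asymmetry knob conflates perceptual precision and decision
  criterion.
- The staircase biases described above are inherent to the specified
  procedure and left uncorrected by design.
- Battery covariates have no task model behind them; only their correlation
  structure is meaningful.
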