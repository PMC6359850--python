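# Methods

This note documents the models, conventions and numerical choices
behind `gaitphase`, in the order the pipeline runs.

## Phase model

A stride is divided into four phases by four gait events, with the
half-open convention `[start, end)` so every in-stride sample carries
exactly one label:

| phase            | interval                                  |
|------------------|-------------------------------------------|
| Loading Response | [initial contact, mid-stance)              |
| Push-Off         | [mid-stance, foot-off)                     |
| Swing            | [foot-off, maximum knee flexion)           |
| Terminal Swing   | [maximum knee flexion, next initial contact) |

The event→phase pairing above is the only assignment of the four events
to the four cyclic phases that is consistent with their temporal order;
we state it explicitly because it is easy to get off-by-one.
The successor map `LR→PO→Swing→TSw→LR` is fixed and shared by the
labeller, the TSVC rules and the event detector.

## Synthetic gait simulator (`synth`)

The simulator emulates the statistical structure of treadmill walking
recorded by thigh/knee sensors; it is deliberately stylized, not a
biomechanical model. Per stride:

* **Knee angle** = baseline (≈3°) + a stance flexion Gaussian bump
  (centre 15 % of stride, amplitude `16°·(v/1.33)^0.7` so stance knee
  motion shrinks monotonically as speed `v` drops) + a swing flexion
  bump peaking near 60° whose sampled argmax *defines* the
  maximum-knee-flexion event, guaranteeing label/template consistency.
* **Angular velocity x** is the scaled time-derivative of the knee
  angle, so it crosses zero at knee-angle extrema; y/z are smooth
  stride-periodic oscillations.
* **Acceleration z** carries a gravity-scale offset (9.81 m/s²) during
  stance that drops during swing; x/y are stride-periodic oscillations
  whose amplitude scales with speed.
* **Stride time** follows `1.1 s · (1.33/v)^0.55` — about 1.1 s at
  self-paced speed, longer for slow walking. No cadence data were
  available to calibrate against, so the exponent was chosen once to
  give plausible 1.1–2.1 s stride times over the 0.4–1.33 m/s range.
* **Surfaces** (level, ±7° slope, ±5° cross-slope) act as mild
  covariates: small offsets to stance amplitude and baseline (slopes)
  or to the lateral channels (cross-slopes). Real slope walking also
  changes timing and ankle strategy; that is out of scope.
* **Variability**: per-stride template jitter and additive Gaussian
  channel noise both scale with `1.33/v`, so slow walking is noisier —
  the regime where recognition is genuinely harder. Event fractions
  default to mid-stance 30 %, foot-off 60 %, maximum knee flexion 73 %
  of the stride (standard gait-cycle conventions; configurable).

Cohort presets mirror the study design they emulate — `training`:
30 subjects × 4 speeds × 5 surfaces × 10 strides, self-paced speed
~N(1.33, 0.04) m/s; `validation`: 12 unseen subjects, self-paced only
~N(1.41, 0.34) m/s, 6 strides per surface — with per-subject amplitude,
timing and baseline offsets. Desk-scale experiments pass smaller
subject/stride counts explicitly; the defaults stay at study scale.

What passing tests on this generator show: that the pipeline recovers
phase structure from signals with the right qualitative shape, ordering
and noise scaling. What they do not show: performance on real IMU data
with soft-tissue artefact, sensor drift, non-Gaussian noise, or gait
pathology. Only the right-limb sign conventions are emulated.

## Preprocessing

Offline label generation filters with a zero-phase (forward–backward)
4th-order Butterworth low-pass at 10 Hz: zero-phase application avoids
shifting gait events in time, at the cost of being non-causal — which
is acceptable offline, and the streaming path classifies raw windows
without filtering. Resampling to the 200 Hz working rate is plain
linear interpolation preserving the first sample exactly.

## Window features

0.1-s windows (20 samples) advanced by 0.01 s (90 % overlap), labelled
by the **last** sample. Conventions chosen where several defensible
readings exist:

* *max difference* = within-window range `max − min` (the min/max of
  some channels are separate features, so the range is a distinct
  statistic);
* *variance* is the population form (windows are complete populations
  of fixed size 20; the choice only rescales);
* *sign-sum* scores exact zeros as 0 (they are neither positive nor
  negative);
* *principal frequency* excludes the DC bin — offset-bearing channels
  would otherwise always report 0 Hz regardless of rhythm — and breaks
  magnitude ties toward the lowest frequency for determinism; a window
  with no non-DC energy reports 0 Hz;
* *peaks* are strict interior local maxima with no prominence
  threshold; plateaus count once, at their first descending edge;
* *correlation* returns 0 when either channel has zero variance.

## Logistic model tree

Induction: binary splits on `feature ≤ threshold`, thresholds at
midpoints between consecutive distinct sorted values, chosen to
maximize plain information gain on the class variable (not C4.5's gain
ratio; with exclusively numeric, binary splits the gain-ratio
correction only rescales by a near-constant split entropy). Ties break
toward the lower feature index, then the lower threshold. Splitting
stops on purity, below `min_instances` (default 15) or when no split
has positive gain; each child must receive ≥ 2 instances.

Leaf models: multiclass LogitBoost with simple linear regression base
learners — per iteration, for each class, a weighted least-squares fit
of the working response on the single best feature, then the standard
`(K−1)/K` centring across classes. Working responses are capped at
|z| ≤ 3 and weights floored at 1e−12. The iteration count is selected
once, at the root, by stratified internal 5-fold cross-validation over
1..200 iterations (fewest iterations wins ties); every child
warm-starts from its parent's committee and runs that many additional
iterations on its own instances. Because every base learner is linear,
the whole committee collapses to one coefficient vector γᵢ per class;
leaves store only γ.

A boosting step that fails to reduce the training deviance is
step-halved (up to 10 times, then boosting stops at that node), making
the training negative log-likelihood non-increasing by construction
rather than only in expectation.

Probabilities: `P_i = exp(F_i)/Σ_j exp(F_j)` over the four phases — the
multinomial normalization whose two-class case is the sigmoid
`e^F/(1+e^F)`. Scores are clipped to ±500 before exponentiation and
probabilities floored at 1e−300 and renormalized, so they are always
finite, strictly positive and sum to 1; neither safeguard can change
the argmax. Ties in argmax resolve to the first class in the fixed
order (LR, PO, Swing, TSw).

Pruning: CART cost-complexity. Weakest-link labelling assigns every
internal node the α at which it collapses (subtree resubstitution
error vs the node's own logistic model — every internal node keeps its
model precisely so it can become a leaf). Candidate α values are the
geometric means of consecutive breakpoints; 5-fold cross-validation
scores each candidate, and the 1-SE rule picks the largest α whose CV
error is within one binomial standard error of the minimum.
Degenerate cases: single-class input yields a single leaf whose class
score is the clip value (probability 1 to double precision); empty
input is an error.

The random seed controls only internal fold assignment; induction is
otherwise deterministic given the data.

## TSVC

Rule A (impossible jump) and Rule B (isolated outlier, one-instance
lookahead) are described in the module docstring. Two boundary choices:
the first three instances pass through uncorrected (the rules need a
3-history), and a non-uniform 3-history passes instances through
unchanged — the correction rules are only defined against a stable
history. Corrections are purely symbolic: classifier probabilities are
never consulted. In evaluation, TSVC is applied per contiguous
recording, never across subject/trial boundaries, where history would
be meaningless. Whether the original formulation delayed emission or
retro-corrected is unstated; this implementation makes the
one-instance lookahead explicit in the streaming contract.

## Evaluation

One-vs-rest per-class metrics from the pooled confusion matrix;
ratios with zero denominators are reported as 0 with an `undefined`
flag (rather than NaN) so the instance-weighted averages
`W_m = Σ mᵢ·Iᵢ / Σ Iᵢ` remain computable while staying auditable.
Stratified 5-fold cross-validation pools held-out predictions over all
folds ("pooled-CV"); a resubstitution report (re-predicting the
supplied training set) is also provided, since both readings of
"reiterating through the supplied training set" are defensible —
pooled-CV is the default because it is the honest generalization
estimate.

## Problem sizes

The test suite and the acceptance script run the end-to-end experiment
at desk scale: a training cohort of 6 virtual subjects × 2 speeds
(1.33, 0.6 m/s) × 3 surfaces × 2 strides (~10 000 windows) and a
held-out validation cohort of 4 unseen subjects at self-paced speeds
(~2 300 windows), sizes at which the full pipeline (including the
nested cross-validations inside LMT training) completes in about a
minute while every class still has thousands of training windows.
Corrupted-stream experiments flip 2 % of eligible positions into
isolated outliers.

## Known limitations

* The simulator's surfaces are mild covariates; it cannot show whether
  the classifier separates surface-specific strategies in real data.
* Tree sizes on synthetic cohorts are small (tens of nodes) because the
  simulator's class structure is cleaner than motion-capture data;
  absolute tree size is reported, never asserted.
* Event detection is label-derived; detecting initial contact or
  foot-off from raw IMU signals is out of scope.
* Static-vs-dynamic state detection and very-slow-walking handling
  (≤ 0.4 m/s) are not implemented.
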