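# Methods

## The measurement model

During a pronator drift test the arm is held still, so over the bandwidth of
interest the accelerometer output is dominated by the gravity reaction.
With the device strapped to the volar wrist (Y along the forearm toward the
fingers, X across the wrist toward the thumb on the right arm, Z out of the
palm), the unit gravity direction g determines the two clinical angles:

* drift `theta = arcsin(g_y)` — 0° for a horizontal forearm, positive when
  the hand drops, 90° when the forearm hangs vertically;
* pronation `phi = atan2(g_x, g_z)` — 0° palm-up, +90° at quarter pronation.

Left-arm devices are mirrored in X on load so that positive pronation means
palm-toward-prone on both sides.  When the forearm is exactly vertical
(g_x = g_z = 0) pronation is undefined; the previous valid value is held and
a warning logged — that posture is outside the test protocol anyway.

**Filter bands.**  All filtering is an order-2 Butterworth applied
forward-backward (zero phase), so angle series are not time-shifted.  Two
cutoffs play different roles:

* *gravity isolation* (`estimate_gravity`, default 1 Hz) captures the purely
  postural orientation; a 10 Hz disturbance of 0.1 g is attenuated to ~1e-4
  of its amplitude.
* *angle extraction* (`stream_to_angles`, default 5 Hz) keeps the few-hertz
  physiological jitter of the held arm in the angle series — otherwise the
  OSC features would measure nothing — while still suppressing wide-band
  sensor noise.  The slow statistics (AVG, MAX) are insensitive to this
  choice.  White sensor noise of SD 0.05 g perturbs extracted angles by
  under 2° RMS even in the narrow 1 Hz band, and by ~1.3° RMS at 5 Hz.

Irregularly sampled but monotonic input is linearly interpolated onto a
uniform grid (default 50 Hz — the field does not agree on a canonical rate;
anything above ~20 Hz is equivalent for these bands).  Non-monotonic
timestamps are rejected, never silently reordered.

## Features

The test lasts 20 s and analysis covers the half-open window [10 s, 20 s):
the first half absorbs the "initial dip", the settling transient under the
device's own weight.  Per arm (WEAK = paretic, CNT = counter side) and per
measure (drift, pronation) three statistics are taken:

* **AVG** — arithmetic mean (degrees);
* **MAX** — *signed* maximum, i.e. the deepest drop / furthest pronation
  reached.  An absolute maximum would conflate corrective overshoots above
  the horizontal with weakness; the signed convention keeps direction.
* **OSC** — RMS of the linearly detrended windowed series (degrees RMS), a
  jitter magnitude invariant under any affine trend.  A direction-reversal
  count is available behind `osc_method="reversals"` for sensitivity
  analyses.

Controls have no paretic side; the non-dominant arm is labelled
weak-equivalent and the convention is recorded in the roster
(`weak_label = nondominant`).

Subjects graded MRC 0–3 cannot resist gravity plus the device's weight and
are excluded from analysis at dataset construction.

## Classifiers

All three families expose `fit(dataset)`, `predict -> {-1, +1}` and a
monotone `decision_score` used for ROC pooling.  Score ties at the decision
boundary resolve to the control class (conservative and deterministic).
SVM and RBFN standardize features to zero mean / unit variance, fit on the
training fold only; the forest consumes raw features.

* **SVM** — polynomial kernel `K(x, z) = (x·z + 1)^d`, default degree 2 and
  C = 1 (degree ≥ 2 because weakness interacts multiplicatively across
  drift/pronation features; both are configuration keys).  The score is the
  signed margin.
* **RBFN** — K prototypes from seeded k-means; widths
  `beta_i = 1 / (2 sigma_i^2)` where `sigma_i` is the within-cluster RMS
  distance floored at half the distance to the nearest other prototype
  (Moody–Darken-style).  The floor matters: a nearly degenerate cluster —
  e.g. a tight control group — otherwise gets a huge beta, every held-out
  point activates nothing, and the network degenerates to its majority-class
  bias.  Output weights are least squares against one-hot class targets;
  prediction is the argmax output node, the ROC score is
  `score(+1) − score(−1)` and `predict_proba` its softmax.  K defaults to 2
  with feature selection and 4 without (the two regimes need different
  capacity); empty clusters are handled by k-means' internal relocation.
  With K = n and distinct inputs the Gaussian design matrix is nonsingular,
  so the network interpolates its training targets exactly.
* **RF** — 100 gini trees, bootstrap sampling, ⌈√m⌉ features per split,
  deterministic per seed.  The positive-class score is the fraction of trees
  voting positive (leaves are grown pure, so sklearn's averaged
  probabilities coincide with votes except on duplicated conflicting rows).

Models serialize to documented JSON (support vectors and dual coefficients;
prototypes, widths and weights; exported tree arrays) and reload into
predictors that reproduce the original decisions.

## Wrapper feature selection

Best-first search from the empty set: an open list ordered by merit, each
expansion evaluating the single-feature additions and deletions of the most
promising unexpanded subset (a forward-only mode exists).  Merit is the
LOOCV accuracy of the wrapped classifier on the candidate columns; the
empty subset scores the majority-class proportion.  The search stops after
5 consecutive non-improving expansions (the common default for this
strategy), when the space is exhausted, or when the incumbent reaches merit
1.0 — exact, since accuracy cannot exceed 1.  Ties break toward smaller,
then lexicographically earlier subsets, so duplicated features collapse to
one.  Subsets are memoized; nothing is evaluated twice.

For the random forest the default merit is **out-of-bag accuracy** instead
of exact LOOCV: OOB is the ensemble's built-in leave-out estimate and costs
one fit per subset rather than n, which is what makes nested selection
inside LOOCV tractable (n_subsets × n forest fits per fold otherwise).
Exact LOOCV merit remains available (`merit="loocv"`), and the oracle tests
that compare best-first against exhaustive enumeration use it.

## Evaluation

LOOCV produces exactly one held-out score per subject; the pooled scores
form one ROC curve (trapezoidal AUC, ties counted half — verified against
concordant-pair enumeration).  Feature selection can be *pooled* (run once
on the full cohort, subset fixed across folds — what small-sample studies
typically report) or *nested* (re-run inside every training fold —
unbiased).  Pooled estimates are optimistically biased relative to nested
ones on average; the suite documents that direction over 50 seeded cohorts
rather than asserting it per cohort.  Group differences use Welch's
two-sample t-test per feature, uncorrected by default to match per-feature
reporting conventions (a `correction=` flag exposes statsmodels'
adjustments).  Relative improvement is `100 (after − before) / before`,
reported to two decimals; the cross-family AUC summary is the mean of the
per-family relative improvements.

## Synthetic cohorts

A subject of severity s ∈ [0, 1] follows

```
theta(t) = dip(t) + s·drift_max·(1 − e^(−t/tau)) + s·osc_amp·sin(2π f t + ph) + sway
phi(t)   =          s·pron_max ·(1 − e^(−t/tau)) + s·osc_amp·sin(2π f t + ph') + sway
```

with the counter arm tracing `coupling` × the weak arm's deterministic
trajectory plus its own sway.  Defaults: drift_max 30°, pron_max 60°,
tau 4 s, osc_amp 5° at 3 Hz, coupling 0.3, sway 0.5° RMS, sensor noise
0.02 g per axis, 50 Hz × 20 s.  The initial dip is a raised-cosine bump
(8°, gone by 3 s) confined to the drift channel — it models postural
settling of the extended arm under the device's weight, which is a vertical
sink, not a rotation; with the default window the features are insensitive
to it within 1 %.  Patients draw s ~ U[0.4, 1] (mild-to-moderate weakness;
MRC 4 / 4+ / 5 assigned by severity thirds), controls hold s = 0.  The
forward sensor model `g = (sin φ cos θ, sin θ, cos φ cos θ)` is the exact
inverse of the extraction geometry, so noise-free round trips recover
ground truth to < 0.5° RMS across the posture range.

What the generator does **not** emulate: true linear (non-gravitational)
acceleration during corrections, sensor bias/scale error and axis
misalignment, tremor spectra broader than a single sinusoid, and
asymmetric bilateral involvement.  Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the modelled phenomenology,
not clinical performance: with every patient at severity ≥ 0.4 the default
cohorts are strongly separable, and all families approach perfect LOOCV
discrimination on them.

## Study sizes and numerical choices

* The end-to-end suite evaluates six seeded default cohorts in both the
  tests and `scripts/acceptance.py` (nested wrapper selection inside LOOCV is the
  dominant cost, ~1 min per cohort per three families); thresholds are on
  cross-cohort means (nested-RF mean AUC ≥ 0.9, selection not reducing any
  family's mean AUC).
* Gravity vectors are validated unit-norm to 1e-6; the RBFN width floor is
  1e-6; search-merit comparisons use an epsilon of 1e-12; undefined rates
  (zero denominators) are reported as NaN with a warning rather than raised.
* Degenerate inputs: empty files, non-monotonic time, streams shorter than
  the filter warm-up or window, single-class training folds, K > n, and
  invalid configuration keys all fail fast with typed errors naming the
  deficit.

## Known limitations

* The angle conventions constitute this package's contract; instrument
  firmware may define device frames differently and requires remapping on
  load.
* OSC depends on the extraction band: narrow it to 1 Hz and jitter is
  filtered out by construction.
* The pooled selection mode reproduces the optimistic bias inherent in
  running selection once on all subjects; use nested mode for unbiased
  estimates.
* AUC differences between classifier families on the same LOOCV folds are
  correlated; the package reports the AUCs and improvements but deliberately
  implements no significance test between correlated AUCs.
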