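# Methods

## Problem and pipeline

The package stages the severity of a Parkinsonian gait from 2-D pose
keypoints alone. A single sagittal-view walk is reduced to two signals —
the signed inter-ankle separation (Type I) and each foot's height above
ground (Type II) — from whose extrema six spatiotemporal features are read
per gait cycle. Because labeled recordings at graded severities are rare,
training data is manufactured: a continuum of synthetic gaits is created by
pointwise linear combination of one normal and one Parkinsonian exemplar,
`l_C = ω·l_P + (1−ω)·l_N`, and each combined gait's feature rows inherit a
stage label from ω by quarter-interval binning (I: ω<0.25, II: <0.50,
III: <0.75, IV: ≤1.0, upper edge closed). Classifiers then learn to map a
single cycle's feature vector to a stage; a whole recording is staged by
majority vote over its cycles.

## Signal conditioning

* **Signed Type I.** Using `x_L − x_R` rather than |distance| makes
  consecutive heel-strike extrema alternate in sign, so "sum of two
  consecutive extremum magnitudes" is geometrically a stride length and
  consecutive extrema spacings are step times. An unsigned distance would
  collapse every other extremum toward zero.
* **Type II orientation.** Image y grows downward, so the trace is flipped
  (`max(y) − y`); ground contact is then a signal *minimum*, and per-foot
  contact minima drive the timing features.
* **Normalization** divides by max |value| (not max value), mapping the
  signed Type I signal into [−1, 1]; lengths are therefore reported in
  normalized amplitude units — no pixel-to-metre calibration is attempted,
  and length features are comparable only within one normalization window.
* **Resampling** is linear interpolation onto a uniform 1000-point grid over
  the window where both exemplars have detections (never extrapolating).
  1000 points over a ~14 s window gives ≈ 70 Hz — comfortably above any
  gait harmonic of interest.
* **FFT denoising** zeroes all Fourier coefficients above a fraction
  (default 0.1) of the half-spectrum, preserving the DC term exactly. At
  the default grid this keeps ≈ 3.5 Hz and below: the stride fundamental
  (0.9–1.25 Hz here) and its first harmonics survive, while pixel jitter
  and 5 Hz tremor are suppressed. The cutoff, like the peak-detection
  settings, is exposed in configuration (`fft_keep_fraction`).
* **Extrema detection** uses a prominence gate (default 0.1 of the
  peak-to-peak amplitude) and a spacing gate (default 0.25 s), followed by
  a cleanup pass that enforces strict max/min alternation by keeping the
  more extreme of two adjacent same-sign extrema. Defaults were chosen so
  that a clean sinusoid at gait frequencies yields exactly one extremum per
  half-cycle while sub-noise ripples are ignored.

## Feature definitions kept literally

Two definitional quirks are retained deliberately:

* **Swing time** here is the spacing of one foot's consecutive contact
  minima — dimensionally a full stride period of that foot, not the
  biomechanical swing phase (which would require stance-end detection that
  the signals do not expose).
* **Double support** is the lag between the two feet's index-paired contact
  minima — roughly a half-cycle phase offset, not the classical dual-stance
  duration. Pairing trims leading minima until the two lists start within
  half a (median) cycle of each other, then pairs index-by-index and takes
  absolute differences.

Both choices keep the features monotone in the underlying gait parameters,
which is what the classifier needs; users comparing against walkway-derived
values should not read these two columns as their clinical namesakes.

## The gait simulator

The packaged exemplar source emulates a treadmill-style sagittal recording:
ankle forward positions are antiphase sinusoids of half-amplitude
`step_amplitude_px` about a static hip midline; ankle/heel heights are
rectified sinusoids of height `foot_clearance_px` with one ground contact
per stride per foot, the feet offset by `phase_offset_rad` (default π, i.e.
evenly alternating feet — double-support lag = φ/(2πf)); every coordinate
receives i.i.d. Gaussian jitter, and distal x additionally a tremor
sinusoid. Defaults (chosen once as the study conditions):

| parameter          | normal | parkinsonian | rationale |
|--------------------|--------|--------------|-----------|
| cadence (stride Hz)| 0.9    | 1.25 (1.39×) | normal stride ≈ 1 Hz; festinating gait is faster |
| step amplitude (px)| 90     | 35 (0.39×)   | shuffling steps less than half length |
| foot clearance (px)| 35     | 12 (0.34×)   | reduced foot lift |
| jitter SD (px)     | 1      | 2            | pose-estimator noise, worse on fast limbs |
| tremor             | off    | 4 px @ 5 Hz  | resting-tremor band |
| duration / fps     | 14 s / 30 | same      | ≈ 12–17 strides per recording |

What the simulator does **not** emulate: missing detections from occlusion,
camera motion, turning segments, left/right asymmetry, stride-to-stride
variability beyond white jitter, and any correlation structure between
features other than that induced by the shared sinusoidal kinematics.
Passing tests on simulated data therefore demonstrate that the pipeline
recovers known generating parameters and that the synthesis/selection/
evaluation machinery is correct — not that the classifier accuracies would
transfer to real clinical video.

A consequence of the cadence contrast: per-ω row counts grow with the
combined gait's cadence, so severe stages collect ~1.5× the rows of stage I
(≈ 33% imbalance at 80 combinations). This is inherent to interpolating
between gaits of different cadence and stays far from needing resampling
techniques; no rebalancing is applied.

## Model selection

Hyper-parameter grids are fixed: KNN `n_neighbors ∈ {1,3,5,7,9,11,13,15}`,
`metric ∈ {euclidean, manhattan, minkowski}`, `weights ∈ {uniform,
distance}`; SVM `C ∈ {0.01, 0.1, 1, 10, 100}`, `kernel ∈ {linear, rbf}`,
`gamma = scale`; GB `n_estimators ∈ {1, 2, 5, 20, 50, 100}`. KNN and SVM
operate on z-scored features (scaler fit inside each CV training fold);
distance- and kernel-based methods need commensurate feature scales, while
tree-based GB uses raw features.

Every grid point is scored by mean stratified 10-fold CV accuracy, but the
CV-best point is *not* automatically the winner: each combination's
learning curve (10 training-size fractions 0.1…1.0, same stratified folds)
is diagnosed, and combinations are examined in descending CV-accuracy order
until one shows a good fit. The diagnosis rule: **overfit** when the final
train−validation gap exceeds `gap_tol` (default 0.05); **underfit** when
the final validation score is within 0.05 of chance *or* the validation
score still improved by more than `plateau_tol` (default 0.01) over the
last third of the size axis; **good fit** otherwise. The gap tolerance was
set above the ~0.04 gap that a well-behaved boosted model shows here while
rejecting memorizers (1-NN and distance-weighted KNN pin training accuracy
at 1.0, making their gap equal 1 − validation accuracy). Dataset-size
selection scans the candidate combination counts {20, 40, 60, 80, 100,
200, 250} in ascending order and keeps the first size with a good-fit
combination.

Seeds thread through fold assignment, the simulator and every stochastic
model component (default 22); identical inputs and seed give byte-identical
dataset CSVs and identical selected hyper-parameters.

## Evaluation

Metrics are one-vs-rest per stage: accuracy, sensitivity, specificity, F1,
PPV, NPV from the binarized counts; zero-denominator cases surface as NaN
tagged "undefined", never as silent zeros. The cumulative summary is the
unweighted macro mean across the four stages (micro averaging would weight
stages by their row counts and does not reproduce standard cumulative
tables). For printed-table comparisons a separate half-up 2-decimal
rounding helper is used; internal values stay at full precision. ROC curves
are one-vs-rest threshold sweeps with trapezoidal AUC; scores come from
neighbor vote fractions (KNN), decision values (SVM) or predicted
probabilities (GB). Feature importance is permutation importance (mean
accuracy drop over 20 seeded shuffles) because it applies uniformly to all
three families.

Recording-level prediction is per-row classification plus majority vote;
vote ties break toward the lower (less severe) stage, a deliberately
conservative clinical default.

## Problem sizes

The default test suite and the acceptance script run entirely on simulated
data: 14 s exemplars at 30 fps, 1000-point signal grids, datasets of
roughly 300–3000 rows (20–200 combinations), full grids under 10-fold CV.
The acceptance script evaluates each family at its selected combination
count (KNN 80, SVM 200, GB 40) and predicts the stage of one unseen walk
simulated with parameters 35% of the way from the normal toward the
Parkinsonian preset.

## Known limitations

* Lengths are unitless (normalized amplitude); cross-recording comparisons
  of length features require a shared normalization window.
* The two Type II timing features are literal re-definitions (see above),
  not their clinical namesakes.
* Linear signal interpolation between gaits of different cadence produces
  beating in intermediate signals; intermediate-ω cycles are therefore more
  heterogeneous than either exemplar, which is the main source of residual
  classifier error near stage boundaries.
* Single-subject, single-view, no turning segments, no freeze-of-gait,
  step-width or velocity features.
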