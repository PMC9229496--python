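# gaitstage

Severity staging of Parkinsonian gait from 2-D pose-keypoint trajectories.

Parkinson's disease progressively alters walking: steps shorten, foot
clearance drops, cadence rises and tremor appears. `gaitstage` turns the
output of a markerless pose estimator (OpenPose-style per-frame JSON, or a
long keypoint CSV) into a four-level severity stage (I healthy, II mild,
III moderate, IV severe — patterned on the Hoehn & Yahr scale) for the
recorded walk. It is aimed at researchers prototyping vision-based gait
assessment who have very little labeled clinical data.

## Method

From the heel/ankle/hip trajectories two sagittal-view signals are built:

* **Type I** — the signed inter-ankle separation `T1(t) = x_L(t) − x_R(t)`,
  whose alternating extrema mark heel strikes;
* **Type II** — each foot's height signal (image y flipped so ground contact
  is a minimum).

Signals are amplitude-normalized, resampled to a uniform grid, low-pass
denoised by zeroing the upper FFT band, and their extrema detected with a
prominence/spacing-gated peak detector. Per gait cycle, six classical
spatiotemporal features follow from the extrema `e_i` at times `t_i`:

| feature        | signal  | definition                   |
|----------------|---------|------------------------------|
| step time      | Type I  | `t_{i+1} − t_i`              |
| stride time    | Type I  | `t_{i+2} − t_i`              |
| step length    | Type I  | `\|e_i\|`                    |
| stride length  | Type I  | `\|e_i\| + \|e_{i+1}\|`      |
| swing time     | Type II | spacing of one foot's minima |
| double support | Type II | lag between the feet's minima|

The scarcity of labeled Parkinsonian recordings is addressed by synthesizing
a severity continuum between one normal exemplar `l_N` and one Parkinsonian
exemplar `l_P`:

```
l_C(t) = ω · l_P(t) + (1 − ω) · l_N(t),   ω ∈ [0, 1]
```

Each combined gait is refeatured and every row labeled by quarter-interval
binning of ω (I: ω < 0.25, II: < 0.50, III: < 0.75, IV: ≤ 1.0). KNN, SVM
and gradient-boosting classifiers are then grid-searched under stratified
10-fold cross-validation, and a hyper-parameter combination is accepted only
when its learning curve shows a *good fit*: terminal train−validation gap
≤ 0.05, validation plateau (≤ 0.01 improvement over the last third of the
size axis) and performance above chance. Evaluation is one-vs-rest:
per-class TP/TN/FP/FN, the six derived metrics, macro averages, ROC/AUC and
permutation feature importance.

A parametric gait simulator (antiphase sinusoidal ankle trajectories,
rectified-sinusoid foot clearance, Gaussian jitter, optional tremor) ships
as the packaged exemplar source; real keypoint recordings are accepted
interchangeably.

## Worked example

```bash
gaitstage simulate --preset normal       --out normal.csv
gaitstage simulate --preset parkinsonian --out pd.csv
gaitstage synthesize --gait-p pd.csv --gait-n normal.csv \
    --n-combinations 80 --out dataset.csv
gaitstage train --dataset dataset.csv --family KNN \
    --out-model knn.joblib --report train.json
gaitstage evaluate --model knn.joblib --dataset dataset.csv --out eval.json
gaitstage predict --model knn.joblib --keypoints pd.csv --out pred.json
```

The train step prints, for example:

```
KNN: cv accuracy 0.956, verdict good_fit; model -> knn.joblib
```

meaning the selected KNN configuration reached 95.6% mean stratified-10-fold
CV accuracy and its learning curve passed the good-fit rule. The evaluate
step prints the macro (unweighted per-class mean) one-vs-rest accuracy, and
`pred.json` holds per-row stages plus a vote summary such as
`{"counts": {"IV": 13}, "modal_stage": "IV"}` — the modal stage is the
predicted severity of the walk.

The same flow is available as library calls (`simulate_gait`,
`prepare_exemplars`, `build_synthetic_dataset`, `train_with_fit_selection`,
`predict_stage`); see `docs/methods.md` for the modelling details and
parameter rationale.

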