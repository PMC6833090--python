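# Methods

## Problem and pipeline

The package classifies the relative intensity of an activity trial — low
(Borg RPE ≤ 11), moderate (12–14) or high (≥ 15) — from four wearable
signal streams: heart rate (bpm, 1 Hz), RR intervals (ms, beat sequence),
electrodermal activity (µS, 4 Hz) and skin temperature (°C, 4 Hz), plus
six static person attributes. The pipeline is: preprocessing → per-trial
feature extraction → z-normalisation and MRMR selection of 15 features →
one of three classifiers with posterior output → optional multimodal
fusion → leave-one-subject-out (LOSO) evaluation.

## Synthetic study generator

No public dataset accompanies this problem setting, so the package ships a
generative model of the study protocol. It is deliberately minimal: its
purpose is to reproduce the *qualitative information structure* the
analysis relies on — heart-derived features track relative strain tightly,
EDA loosely, temperature weakly — not to be a biophysical simulator.

* **Cohort.** Default 22 participants; age ~ Normal(29.8, 3.2) rounded and
  clamped to the 18–40 inclusion window; BMI ~ Normal(25.3, 2.6);
  P(male) = 0.773; resting HR ~ Normal(62, 7) clamped to [45, 85] bpm.
  Heights by sex (men 178 ± 7 cm, women 165 ± 6 cm) and weight derived
  from BMI. A `fitness` scalar ~ Uniform(0.75, 1.0) models self-selected
  pace by scaling the intensity each trial type reaches. Habitual-activity
  status is drawn with probabilities (0.2, 0.3, 0.5) for sedentary /
  insufficiently active / sufficiently active. These distributional
  choices beyond the cohort means/rates are the package's own.
* **Protocol.** Up to 7 weekly sessions of five trials: sit/stand 300 s,
  comfortable walk 300 s, brisk walk 300 s, jog 180 s, run 120 s.
  Recovery periods are not simulated: each trial starts from resting HR,
  consistent with a protocol whose rests let HR return to baseline.
* **Heart rate.** First-order kinetics HR(t) = HRss − (HRss − HRrest)
  e^(−t/τ), τ = 40 s, toward HRss = HRrest + f·(HRmax − HRrest) with
  HRmax = 208 − 0.7·age and target heart-rate-reserve fractions
  f = (0.05, 0.35, 0.55, 0.75, 0.90)·fitness for the five trial types.
  White noise (σ = 1.5 bpm) is added and the series clipped to
  (30, HRmax].
* **RR intervals.** Generated as a beat sequence (not by inverting the
  1 Hz HR trace, so beat-to-beat statistics are well defined): each beat
  has mean 60000/HR(t) ms, a respiratory oscillation at 0.25 Hz with
  amplitude 30·(1 − 0.8f) ms, and white noise with coefficient of
  variation 0.05·(1 − 0.85f) — variability shrinking with intensity is
  the vagal-withdrawal analogue that makes rMSSD/SDSD informative.
  Intervals are clipped to (300, 2000) ms.
* **EDA / temperature.** Tonic first-order rises (τ = 60 s / 120 s)
  toward baseline + gain·f^1.3 (gain 6 µS) and baseline + 0.8·f °C, with
  per-participant baselines derived from a stable hash of the participant
  id and white noise (0.05 µS / 0.05 °C). The literature gives little
  distributional detail for these responses; the defaults are plausible
  placeholders exposed in `SimulationConfig` rather than asserted as
  faithful.
* **RPE.** Borg's classical HR ≈ 10 × RPE correspondence:
  RPE = round(steady-state HR / 10 + ε), ε ~ Normal(0, 0.7), clamped to
  [6, 20], where steady state is the last 60 s of the trial. Numpy's
  round-half-to-even applies at .5 boundaries.
* **Exclusions.** Each scheduled trial is independently marked
  missing/incomplete, missing-sensor, or invalid-RPE (forced rating < 10),
  in that precedence order, at default rates 109/770, 21/661 and 25/640 —
  the per-stage loss proportions of the emulated protocol's ledger.

What the generator does **not** emulate: motion artefact bursts, sensor
drift and detachment, ectopic beats, inter-day within-person variation,
weather/ambient effects on EDA and skin temperature, and any decoupling of
perceived effort from heart rate (affect, caffeine, medication). Passing
tests therefore show the pipeline recovers planted structure under clean
conditions; they do not certify field accuracy.

## Preprocessing

A centered moving average with a window of round(span × rate) samples
(span 5 s: 5 samples at 1 Hz, 20 at 4 Hz) smooths HR, EDA and
temperature; the window is truncated symmetrically at the series edges.
The RR sequence is *not* smoothed — averaging would destroy the
successive-difference statistics. The first and last 10 s of every trial
are discarded (RR intervals whose onset falls in a trimmed zone are
dropped). Offline analysis justifies the non-causal centered filter.

## Features

48 features per trial (names in `relpa.features.MODALITY_GROUPS`):

* **HR bpm stream (10)** — mean, variance, SD, skewness, kurtosis,
  median, on-response and off-response (least-squares HR slope in bpm/s
  over the first and last 30 s of the window — the numerical-gradient
  family), and the number of strict sample-to-sample increases
  (resp. decreases) divided by window length in seconds.
* **RR time domain (10)** — the six moments plus SDSD (SD of successive
  differences), rMSSD, pNN20 and pNN50 with *strict* inequality
  ("differ by more than x ms").
* **RR frequency domain (10)** — the tachogram (beat time, RR) is
  cubic-interpolated onto a 4 Hz grid, mean-removed, and its PSD
  estimated by Welch's method (64 s Hann segments, 50% overlap — the
  shortest analysis window, 100 s for the run trial, still yields two
  segments). Band powers by trapezoidal integration over VLF 0–0.04,
  LF 0.04–0.15, HF 0.15–0.40 Hz; aTotal = aVLF + aLF + aHF by
  construction; relative (pX) and normalised (nLF, nHF) powers and LF/HF.
  Ratios whose denominator is below 1e-9 ms² (numerically flat spectrum)
  are NaN-flagged and imputed later.
* **EDA / temperature (6 each)** — the six moment/order statistics.
* **Person (6)** — height, weight, age, BMI, sex (male = 1), activity
  status coded ordinally 0/1/2.

Estimator conventions: variance/SD use the sample (n−1) denominator
everywhere including SDSD; skewness and kurtosis are bias-uncorrected
moment estimators, kurtosis non-excess (normal → 3) — the common default
of the era's analysis tooling; both defined as 0 for zero-variance input.
Feature windows are either the whole trimmed trial (default — matching a
rating given for the entire trial) or its last 60 s (steady-state
comparison mode); in the latter, every beat overlapping the final 60 s is
retained so the tachogram covers the full window.

## Selection

Features are z-scored (zero-variance columns flagged and centred only) and
NaNs imputed with the training-set median. MRMR uses the greedy MID
(difference) criterion — at each step argmax over unselected f of
I(f; class) − mean over selected s of I(f; s) — with plug-in mutual
information after rank-based equal-frequency discretisation into 10 bins
(ties share bins, so any order-preserving transform gives identical
selection). Ties break by higher relevance, then lexicographic name; the
procedure is fully deterministic. MID over MIQ: no quotient instability
when redundancy approaches zero. Selection scope is configurable:
`complete` (fit once on the whole dataset — mirrors how such analyses
have often been run, but leaks test information) or `train_only`
(recommended; used by the acceptance checks and the reported grids).

## Classifiers

All three consume the same 15-column selected matrix.

* **SVM** — one-vs-rest binary RBF SVMs, C = 1, γ = 1/n_features, each
  Platt-calibrated (sigmoid, internal CV) and renormalised across classes.
  A sequential "one class, then the next" cascade is replaced by standard
  max-posterior OVR.
* **Random forest** — 100 trees (50/150 accepted alternatives);
  posterior = tree-vote fraction.
* **Neural net** — one hidden layer of 7 units, 3-way softmax output,
  ≤ 250 epochs, learning rate 0.01 (a printed source value of 0.00 is a
  typo — a zero learning rate cannot train). The input layer is sized to
  the actual feature count (15 after selection).

Training rows are canonically sorted before fitting so predictions are
invariant to caller row order; all stochastic elements take a seed.
Posterior ties break toward the higher intensity class — conservative for
safety-monitoring applications.

## Fusion

* **Feature fusion** — set-semantics column concatenation of the modality
  groups (person columns de-duplicated), then selection + one classifier
  on the merged matrix.
* **Decision fusion** — one classifier per modality;
  weight(m, c) = per-class F1 (0–1) of modality m's classifier on
  training participants it had not seen, from an internal subject-grouped
  cross-validation pass (default 5 groups; setting groups to None gives
  an exact inner leave-one-subject-out at ~4× the cost — the 5-group
  default keeps the full grid at desk scale with the same
  subject-independence). Inner folds reuse the outer fold's fitted
  normaliser and selected features. At test time
  score(c) = Σ_m weight(m, c)·posterior(m, c), argmax wins. The weighting
  is one reading of "class-based weights from training performance"; the
  exact historical formula is not recoverable, so additive and
  product-of-experts variants are exposed via `fusion_rule` for
  sensitivity checks. A single-modality "fusion" reduces exactly to the
  base classifier.

## Evaluation

LOSO: each participant's trials form one test fold. Metrics are computed
from the confusion matrix pooled over folds (per-fold macro-F1 lists are
retained and exported for downstream statistical comparison); per-class
precision, recall and F1 are reported in percent, with 0 and a flag when
a denominator is zero. The headline score is the unweighted (macro) mean
F1 over the three classes — the convention is stated because pooled
vs fold-averaged and macro vs weighted F1 genuinely differ; per-class
values are always reported so any convention can be recomputed.

## Problem sizes and runtime

The documented default grid — 22 participants × 7 sessions, 7 modality
combinations × 3 classifiers × feature and decision fusion under
`train_only` selection — completes in roughly 5 minutes on one CPU; the
test suite's end-to-end checks run the same grid once and reuse it. The
decision-fusion degradation demonstration uses a 22 × 4 study with EDA
gain 0.1 µS and temperature gain 0.02 °C, making those modalities
near-uninformative relative to their noise.

## Known limitations

* The generator's EDA/temperature response shapes and noise levels are
  plausible but unvalidated; conclusions about those modalities' absolute
  usefulness should not be drawn from synthetic runs.
* RPE is generated from heart rate, so the simulated ceiling for
  HR-based classification is optimistic relative to field data, where
  perception and HR can decouple.
* The `complete` selection scope reproduces a leakage-prone historical
  practice and inflates scores; it is not the package default for
  reported results.
* Class imbalance (moderate is the rarest class) is left unweighted, and
  no hyperparameter search is performed — none is part of the emulated
  configuration.
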