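# Methods

`emomeg` re-creates, as tested reusable code, a sensor-level MEG analysis
for discriminating a small patient group from healthy controls: evoked and
oscillatory power features per magnetometer, L1-penalized logistic
classification with leave-one-subject-out penalty selection, repeated
stratified cross-validation with Bonferroni-simultaneous percentile
intervals, and a rank-sum comparison of picture ratings.  Because no
recordings of this kind are publicly deposited, the package ships a
synthetic cohort generator that serves as the test bed for every stage.

## Synthetic cohort model

The generator emulates *cleaned* epochs — what a preprocessing chain
(artifact rejection, down-sampling, band-pass) would hand to feature
extraction — for 17 controls and 16 patients, three stimulus categories
(pleasant / neutral / unpleasant), and 45–55 trials per subject and
category.  Epochs span the half-open window [−1000, +1500) ms at 250 Hz
(625 samples, onset at index 250; the half-open convention avoids a
duplicated boundary sample).  Each trial is the sum of three independent
parts, in arbitrary consistent field units:

* **Background noise** with a 1/f power slope (flat below 1 Hz, zero DC),
  unit variance, independent across channels and trials.  Spatial
  correlation of real sensor noise is deliberately not modeled: the
  classifier operates channel-wise and no stage depends on cross-channel
  noise structure.
* **Evoked component**: a Gaussian-windowed 5 Hz sinusoid (envelope
  σ = 80 ms), zero before stimulus onset, latency drawn once per category
  from U(100, 400) ms.  Its spatial topography (U(0.2, 1) per channel) is
  shared by all subjects; each subject × category carries a multiplicative
  amplitude jitter with a 20% coefficient of variation.  Base amplitude is
  2.0 noise SDs, giving a realistic single-trial SNR where the evoked
  response becomes clearly visible only after trial averaging.
* **Band-limited oscillations** in each filter-bank band (delta 1–4,
  theta 5–8, alpha 9–14, beta 15–30, gamma 31–45 Hz), each with amplitude
  0.5 noise SDs.  Background and oscillations are drawn jointly as one
  complex spectrum whose per-bin variance is the sum of the component
  variances (the sum of independent Gaussian processes), which makes
  generation a single inverse rFFT per trial block.

Group effects are planted multiplicatively on a chosen channel subset and
(optionally) a chosen category subset: patients' evoked amplitude is
divided by `erf_amplitude_ratio` and their per-band oscillation amplitude
by `sqrt(band_power_ratio)`, so ratios read as control:patient ratios and
all-ones reproduce the exact null.  All randomness flows through explicit
`numpy` SeedSequences; identical (spec, effect, seed) triples are
bit-identical.

Ratings are modeled on the 7-point SAM scale (valence 1 = most pleasant;
arousal 1 = relaxed).  Each picture has a latent value drawn around its
category mean (valence 2.2 / 4.0 / 5.8; arousal 4.8 / 2.6 / 5.2) with
between-picture SD 0.15; each rating adds logistic noise (scale 0.8) and is
rounded and clipped to 1–7.  Patients' pleasant-category latents can be
shifted (`valence_shift_pleasant`, `arousal_shift`).  Two patients are left
incomplete by default (a random fifth of their rows dropped) to exercise
the exclusion path.  The between-picture SD was fixed once by a null
calibration: because both groups rate the *same* pictures, shared picture
latents correlate the two per-picture median vectors and make the rank-sum
comparison conservative, while integer medians tie heavily; SD 0.15 keeps
the pleasant-category null rejection rate at the nominal 5% (within
binomial 99% bounds over 500 replicate cohorts) while leaving neutral
per-picture medians overwhelmingly 4.  What the generator does **not**
emulate: sensor geometry and spatially correlated noise, artifacts,
between-subject topography differences, rating anchors/response styles.
Passing tests therefore demonstrate correctness of the pipeline's
*mechanics* and calibration under an idealized signal model, not
performance on real recordings.

## Feature extraction

Eighteen feature sets are built per cohort: for each category, the mean
squared ERF per channel over the first post-stimulus second, plus the mean
band power for each of the five bands — each a subjects × channels matrix
(33 × 102 at default geometry).

* Baseline correction subtracts the per-trial, per-channel mean of the
  1000 ms pre-stimulus interval.
* The ERF is the trial average low-passed at 45 Hz (zero phase); ERF power
  squares *after* averaging — averaging single-trial power is a different
  quantity and is not used.
* Band power band-passes each trial, squares, averages over the
  [0, 1000) ms window (250 samples), then averages trials.
* All filters are zero-phase frequency-domain masks: the rFFT is
  multiplied by a raised-cosine band edge with transition width
  max(0.25 × edge frequency, 1 Hz) and half gain exactly at the edge.  A
  time-domain FIR of equivalent sharpness for the delta band would need an
  impulse response longer than the 2.5 s epoch, so the frequency-sampling
  form is used for every band; the 1 s pre-stimulus and 0.5 s post-window
  margins absorb the (circular) edge ringing.  Whether the original
  sensor-level protocol computed time-resolved band power or a windowed
  PSD is not derivable from its description; windowed time-domain power is
  the choice here and is fixed by the oracle tests (a 10 Hz unit sinusoid
  yields alpha power 0.5 and delta power < 0.01).

## Penalized logistic classification

Controls are class 1, patients class 0.  The model is binary logistic
regression fitted by minimizing the summed negative log-likelihood plus
λ·Σ|β_m| (intercept unpenalized).  Predictors are standardized to zero
mean / unit variance using *training* statistics only; the fitted
standardization travels with the model.

The solver is iteratively reweighted least squares with an inner cyclic
coordinate descent on the weighted quadratic surrogate (soft-threshold
updates, active-set passes, warm starts along the penalty path).  Numerical
choices: IRLS weights floored at 1e-5; convergence when the largest
coefficient change in a full sweep is below 1e-7 (at most 1e4
reweightings); coefficients with magnitude below 1e-12 snap to exact zero
so sparsity counts are well defined; coefficients are bounded at ±50 on
the standardized scale, reachable only under (quasi-)separation, which
also triggers an early exit on a likelihood plateau and a convergence
warning.  The solver is verified against a brute-force grid minimizer, a
Newton maximum-likelihood solver at λ = 0, an independent L1 solver
(sklearn saga), and the KKT conditions.

λ is selected on a 100-point log-spaced grid from the data-driven λ_max
(smallest penalty with all slopes zero) down to 1e-4·λ_max, by mean
held-out binomial deviance over leave-one-subject-out folds, **under the
constraint that the full-data refit keeps at least two nonzero slopes**
(univariate features were not considered reliable discriminators for this
problem).  Ties go to the largest (sparsest) penalty; the constraint is
evaluated on the full-data refit because that is the model actually
deployed.  A one-standard-error rule is available as an option
(`rule="1sd"`) but the minimum-deviance rule is the default.

## Performance evaluation

At the selected λ, performance is estimated by repeated stratified k-fold
cross-validation (defaults k = 16, 1000 repetitions): per repetition,
fresh class-stratified folds (round-robin dealing after a within-class
shuffle; the deal cursor carries across classes so fold sizes differ by at
most one overall and per class); per fold, standardize on the training
split, refit at λ, classify held-out subjects at probability 0.5.  All N
held-out predictions of a repetition pool into one
accuracy/sensitivity/specificity triple (2-subject folds make per-fold
rates ill-defined).  Sensitivity is the true-positive rate for controls,
specificity the true-negative rate for patients; accuracy·N =
sensitivity·N₊ + specificity·N₋ holds exactly.  Medians and equal-tailed
percentile intervals over repetitions are reported at the
Bonferroni-widened individual level 1 − (1 − 0.95)/6 ≈ 99.2% so that six
intervals are simultaneously valid at 95%.  Repetition r draws folds from
seed base + r, making the whole distribution reproducible.

λ is selected once on the full data and held fixed across repetitions,
mirroring the deployment protocol; `nested=True` re-selects λ inside every
training split for users who want a leakage-free estimate.

**A caution on interval coverage.**  Repeated cross-validation on a single
33-subject cohort resamples fold assignments, not subjects.  Its percentile
interval therefore brackets the *cohort's* cross-validated accuracy — which
under the null deviates from 0.5 by the binomial spread of 33 exchangeable
subjects (SD ≈ 0.5/√33 ≈ 0.09, plus selection effects) — and not the
population chance level.  In simulation, the 95%-simultaneous interval
covers 0.5 in only about half of null cohorts, essentially independently of
montage size, trial count, or SNR.  These intervals quantify resampling
stability, not population-level uncertainty; a permutation test would be
the appropriate inferential tool and is out of scope here.

## Rating comparison

For each category × dimension, each picture's median rating is computed
within each group over complete raters only (incomplete subjects are
dropped entirely; even-cardinality medians use the mean of the middle
two), and the two 60-length median vectors are compared with the two-sided
Wilcoxon rank-sum test: exact null distribution when the pooled sample is
≤ 12 and tie-free, otherwise the tie-corrected, continuity-corrected
normal approximation (delegated to `scipy.stats.mannwhitneyu`; an
exhaustive enumeration oracle verifies the exact path in the tests).  At
these sample sizes the doubled discrete tail of the exact test and the
continuity-corrected normal can differ by up to ≈ 0.09 in two-sided
p-value (worst at 2-vs-2; ≈ 0.04 at 2-vs-8), converging below 0.025 once
both groups have ≥ 4 members with ≥ 9 total — the tests characterize this
explicitly.  The six p-values are reported raw; the output flags the
absence of a multiplicity correction.

## Pipeline

`run-all` executes simulate → extract → select → evaluate → ratings from a
single YAML configuration; each stage derives its seed as
SHA-256(global seed, stage name) mod 2³¹−1, so stages are independently
reproducible.  Outputs (epoch arrays + JSON sidecars, feature CSVs, model
JSONs, metric JSONs/CSVs, the ratings report) are declared in a manifest
with SHA-256 digests.  The manifest is timestamp-free by design so that
re-running a configuration yields byte-identical digests; wall-clock times
go to the log.  Real data enter either as feature CSVs in the documented
layout or as MNE-readable FIF epoch files, which are routed through the
identical feature code.

## Problem sizes used in the shipped checks

The full 33 × 102 × (45–55 trials) geometry is exercised once per test run
(feature-set construction).  Replicate-heavy checks keep the 17 + 16
subject geometry — it determines the resampling structure — and shrink
only channel and trial counts, which set SNR and compute: null-calibration
cohorts use 16 channels and 8–10 trials (200 cohorts, 100 CV repetitions
each); recovery cohorts use 24 channels, 15–18 trials, and a 2.5× evoked
amplitude ratio on 6 channels of the pleasant category (50 seeds).  The
acceptance script reports the same quantities at slightly smaller
replicate counts.

## Known limitations

* No source-space or sensor-geometry modeling; channels are abstract
  indices.
* The λ-selection → evaluation protocol reuses the full sample for the
  scalar penalty choice; the nested option removes this at ~N× cost.
* Percentile intervals from repeated CV understate population uncertainty
  (see above).
* Exact rank-sum p-values are only used for very small groups; per-picture
  median vectors (n = 60 per group) always take the approximate path, and
  their pairing over shared pictures makes the test conservative when
  between-picture variance is large relative to median noise.
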