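# Methods

`chromadecode` implements a time-resolved multivariate decoding analysis for
epoched multi-sensor recordings (MEG-style) of responses to colored stimuli,
together with a synthetic evoked-response generator that makes every stage of
the pipeline testable without recorded data. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
cohort does and does not establish about real recordings.

## Stimulus colorimetry

Stimuli live in the cone-opponent (DKL) space: four hues on the intermediate
chromatic directions — 45° (pink), 135° (blue), 225° (green), 315° (orange) —
crossed with two luminance polarities (+20°/−20° elevation; a 25% Weber
increment or decrement against a 33.5 cd/m² neutral background). The azimuth
fixes the sign pair of the (L−M, S) modulation: pink (+,+), blue (−,+),
green (−,−), orange (+,−); pink/green and blue/orange are therefore
sign-opposite on **both** cone-opponent axes.

`canonical_stimulus_set` builds the 8 stimuli abstractly: each hue displaces
the background by ±`lm_modulation`/2 on L and M (opposite signs, leaving the
luminance channel L+M untouched) and ±`s_modulation` on S; the light/dark
members scale all three cone excitations by 1 ± `lum_contrast`. This makes
the Weber contrast exactly ±`lum_contrast` and the light/dark cone contrast
(|ΔL/ΣL| + |ΔM/ΣM| = 2·`lum_contrast`) identical across hues. A full
display-calibration chain (xyY→LMS→DKL matrices, gamma correction) is out of
scope; cone excitations are accepted as given. Contrast strength converts to
detection-threshold units by dividing by 0.014 (luminance) or 0.001724
(chromatic), both in |L|+|M| cone-contrast units; the S cone is excluded from
the contrast definition to match those threshold data.

## Synthetic evoked responses

Each subject's per-trial signal is a sum of two spatiotemporal components
plus noise (see `simulate.SimulationConfig` for every parameter):

* **Polarity code** — sign(polarity) × a spatial pattern composed of a
  hue-invariant map (`amp_polarity_shared`, default 4 fT), a hue-specific map
  (`amp_polarity_hue_specific`, 1.2 fT), and two cone-mechanism maps gated by
  the hue's (L−M, S) signs (`beta_LM`, `beta_S`, 0.8 fT each), multiplied by
  a temporal profile peaking at `polarity_latency` (100 ms).
* **Hue code** — for each chromatic axis, sign(axis) × a polarity-invariant
  map (`amp_hue_shared`, 3 fT) plus a polarity-specific map
  (`amp_hue_polarity_specific`, 2 fT), multiplied by a later profile peaking
  at `hue_latency` (120 ms).

The shared maps carry the feature-invariant (generalizing) part of each
code; the feature-specific maps make identity decoding exceed generalization
decoding; the cone-mechanism maps make polarity generalization degrade with
the number of sign axes flipped between train and test hues (worst for
pink↔green and blue↔orange, whose patterns fully reverse).

Temporal profiles are gamma-shaped transients (shape 16, i.e. ≈26 ms SD at
100 ms latency) with unit peak at the configured latency, plus (i) an offset
transient at `stimulus_duration` + latency, scaled 0.7 for polarity and 0.3
for hue so the stimulus-cessation response is prominent for polarity and
weak for hue, and (ii) a sustained plateau that rises `sustain_delay`
(30 ms) after the peak and decays with `sustain_tau_*` after stimulus offset
(30 ms polarity vs 150 ms hue — the hue code is the sustained one). The
plateau is delayed past the transient peak deliberately, so the profile's
argmax stays pinned at the configured latency and implanted latencies are
recoverable from decoding curves; gains (0.25 polarity, 0.45 hue) keep every
secondary feature below the primary peak.

Noise is white Gaussian per sensor and sample (`noise_sd`, 200 fT — a
typical single-trial sensor noise magnitude), optionally AR(1) over time
(variance-preserving; default off, white noise suffices for calibration).
Amplitudes were fixed once so that at desk scale (tens of trials per
condition, 64 sensors) family-average decoding peaks land in the 0.75–0.92
range — informative but off ceiling — and the 100/120 ms latencies are
recoverable. Spatial maps are drawn i.i.d. standard normal per subject
(decoding is within-subject throughout, so no shared sensor geometry is
needed). All randomness derives from `SeedSequence([seed, subject_index])`:
identical configuration and subject index give bit-identical data regardless
of cohort size.

**What the generator does not emulate:** spatially correlated sensor noise,
magnetometer/gradiometer unit structure, trial-to-trial latency jitter,
eye-movement or cardiac artifacts, and subject-level amplitude/latency
variability beyond independent spatial maps. Passing tests therefore show
the *pipeline* is correct and calibrated, not that real MEG data will reach
any particular accuracy; the headline numbers of the study this emulates
depend on the recorded dataset and are not reproduced here.

## Preprocessing

Trials with any sensor sample outside an amplitude range (default
0.1–8000 fT) can be dropped (`reject_artifacts`); the workflow leaves this
screen disabled by default because on white-noise synthetic data every trial
contains near-zero samples and the screen, which targets recording
artifacts such as flat or jumping channels, would reject everything. Trials
are then subsampled without replacement to equal counts per condition
(375 in the emulated design), baseline-corrected by each trial's per-sensor
pre-stimulus mean, and averaged into non-overlapping 5 ms bins, half-open
[start, start+5) and labeled by start time. The default −200…600 ms epoch
gives 160 bins with stimulus onset opening bin 40.

## Decoding engine

The classifier is the maximum-correlation-coefficient rule: average the
training pseudo-trials of each class into a mean population vector, assign
a test vector to the class with the larger Pearson correlation. Exact ties
break to the lower class index and are counted on the results object.
Correlation against a zero-variance vector is defined as 0.

Cross-validation follows the pseudo-trial scheme: per run, each condition's
trials are randomly partitioned into `n_splits` disjoint sets of
`trials_per_split` trials (5 × 75 in the emulated design), each averaged
into one pseudo-trial; identity problems use leave-one-set-out folds, and
the whole procedure repeats for `n_runs` (50) independent partitions.
Per fold:

* **z-scoring** — per sensor, using the mean and SD of the training
  pseudo-trials pooled over *all* time bins, applied to train and test data
  at every bin. This neutralizes per-sensor gain/offset (so magnetometers
  and gradiometers can be pooled); the engine is exactly invariant to
  positive per-sensor affine transforms of the raw data.
* **sensor selection** — the `n_selected_sensors` (25) sensors whose
  activity covaries most with the training labels at that bin, ranked by
  one-way ANOVA F (equivalently, ascending p: group sizes are equal, so the
  ranking is monotone in F). Zero-variance sensors are excluded before
  ranking; if within-group degrees of freedom vanish (single pseudo-trial
  per class) the score falls back to |mean difference|. Selection uses
  training data only and the same set is applied to train and test.

Generalization problems train on **all** pseudo-trial sets of the train
conditions and test on pseudo-trial sets built from the (disjoint) test
conditions, so no trial ever contributes to both sides; the "fold" index
ranges over the test sets. Accuracy at each bin is the average over runs,
folds, and the two test pseudo-trials.

Temporal generalization applies each train-bin classifier — with its
train-bin sensor selection and the training z-statistics — to test
pseudo-trials at every bin; the diagonal reproduces the per-bin curve
exactly under shared seeds. Pseudo-trial assignment per run comes from
`SeedSequence([cv_seed, run])` with conditions drawn in problem order;
this seeding is part of the engine's contract (the brute-force oracle in
the test suite relies on it).

`subsample_to_match_peak` bisects the per-condition trial fraction
(pseudo-trial counts rescaled proportionally) until the initial-window peak
matches a target within tolerance, for comparing time courses between
problems of unequal strength.

## Resampling inference

* **Subject bootstrap** — resample subjects with replacement (B = 1000),
  average; per-bin 95% percentile band; peak latency recorded per resample
  within a configurable initial-peak window. Peak-latency comparisons are
  **paired**: both summaries must be built from the same resample draws, and
  the one-sided p is the proportion of (A−B) differences ≤ 0, reported as
  "p < 1/B" when the proportion is zero. The initial-peak window defaults to
  0–250 ms; analyses on the synthetic cohort at high SNR use 0–200 ms
  because the implanted cessation transient (stimulus offset + latency ≈
  216–236 ms) would otherwise be picked up as the initial peak — the
  boundary between onset and offset responses is a design choice, not a
  measured quantity.
* **Sign-permutation cluster test** — statistic: mean over subjects of
  (accuracy − chance); null: independent per-subject sign flips (1000);
  pointwise one-sided p thresholded at the cluster-defining p (0.01) to
  form clusters (runs in 1D, 4-connected components in 2D matrices);
  cluster statistic: summed mean effect (mass); cluster p: proportion of
  permutations whose maximum cluster mass reaches it; significant at
  α = 0.05. Monte-Carlo p-values use the add-one convention; when
  2^n_subjects ≤ n_perm all assignments are enumerated and the test is
  exact. Differences between conditions (e.g. hue vs polarity TG matrices)
  use the same machinery on per-subject difference arrays.
* **Onset** — first run of ≥ 4 consecutive significant 5 ms bins at or
  after stimulus onset; peak — most accurate bin in the initial-peak
  window, ties to the earliest bin.
* **Within-subject shuffle null** — condition labels of the problem's
  trials are shuffled and the *same* estimator (full CV scheme, same run
  count) is re-run, 1000 times; per-bin add-one p-values are BH-FDR
  corrected (q = 0.05) and reported bins must additionally sit in runs of
  ≥ 4 consecutive significant bins. Note the p-value floor is
  1/(n_null+1): with 160 bins the BH threshold can only be cleared when
  n_null is on the order of 1000, which is why the emulated design uses
  that number.
* **Test–retest** — pairs of disjoint trial samples at 10/25/40/50%
  fractions, decoded independently (pseudo-trial counts rescaled), Pearson
  correlation of the two curves, 5 repetitions per fraction.
* **Counterphase statistic** — Spearman correlation of the first-differenced
  curves over a 116 ms window after onset; **subject consistency** — each
  subject's post-onset curve Spearman-correlated with bootstrap means of the
  other subjects (n−1 with replacement, 1000 draws), averaged.

## Model layer and workflow

`SubjectDecoding`/`CohortDecoding` wrap the engine in fit-then-inspect
objects: `CohortDecoding(binned, problems, cv).fit()` returns results
carrying per-subject curves, family averages, paired bootstrap and
cluster-significance methods, and a `summary()` table (peak accuracy and
CI, peak time and CI, onset, significant-bin count, tie count per problem).
The `chromadecode` CLI (`simulate`, `decode`, `stats`, `report`) drives the
same objects from a YAML/JSON config; epoch containers are single-file
HDF5 (+ JSON sidecar), results are TSV (+ JSON sidecar with seeds and a
config hash), and an adapter imports sensor epochs from FIF files.

## Problem sizes used in the shipped tests

The test suite runs the full pipeline at desk scale on one CPU: cohorts of
1–8 subjects, 12–64 sensors, 16–160 trials per condition, reduced CV
(2–5 splits, 1–40 runs). The chance-calibration run uses 2 subjects ×
64 sensors × 80 trials with 4 × 20 splits and 10 runs; the
latency-recovery run uses 8 subjects × 64 sensors × 120 trials with
5 × 24 splits and 40 runs (at larger trial counts the polarity curve
saturates and its argmax biases late, shrinking the recovered lag);
family-wise error control is checked over 250 null cohorts of 8 × 160-bin
curves with 200 permutations. These sizes are analysis choices that keep
the statistics informative while the suite stays fast.

## Known limitations

* Accuracy magnitudes on synthetic data are not comparable to recorded
  data; only orderings, latencies and calibration are meaningful.
* The within-subject permutation null becomes heavy-tailed at very high
  SNR with few trials (label-imbalance in pseudo-trial sets carries real
  signal); the implementation matches the estimator between observed and
  null runs, but small-trial regimes remain intrinsically coarse.
* With equal cone-mechanism gains and no shared polarity map, single-axis
  hue changes leave train and test patterns near-orthogonal, so 1-axis
  polarity generalization sits at chance under a correlation classifier
  (2-axis changes reverse the pattern and fall below chance); the
  generator reproduces the "both-axes weakest" structure, not
  above-chance 1-axis decoding in that extreme configuration.
* 5 ms binning quantizes peak latencies; paired bootstrap comparisons can
  tie at zero, which the "≤ 0" convention counts against the alternative.
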