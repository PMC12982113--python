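# Methods

This note documents the models, conventions and design choices behind
`easleep`: a pipeline for resting-state EEG microstate analysis in a
chronic-insomnia treatment cohort, with a machine-learning stage that
predicts treatment response from baseline microstate features, and a
synthetic-data generator that makes every stage testable against known
ground truth.

## The microstate model

Resting EEG is modeled as a sequence of a few quasi-stable scalp
topographies — microstates — each lasting tens of milliseconds. We use the
classic four-class model (classes A–D): A is a left-occipital to
right-frontal gradient, B its left/right mirror, C a left/right-symmetric
fronto-occipital pattern, and D a fronto-central maximum. Segmentation is
polarity-invariant throughout: a map and its negation belong to the same
class, because the generating dipole's sign is not identified at the scalp.

The analysis chain:

1. **Preprocessing.** Input EEG is resampled to 256 Hz, band-passed 1–45 Hz
   and band-stopped 48–52 Hz with 4th-order Butterworth filters applied
   forward–backward (zero phase; the conventional choice where no filter
   family is prescribed), optionally screened for high-amplitude 2-s epochs
   (disabled by default; synthetic data is artifact-free). A second stage
   narrows to 2–20 Hz and re-references to the common average. Artifact
   component removal on real data is a manual, decomposition-based step that
   cannot be reproduced computationally; `artifact_stage` is the no-op hook
   where real-data users can plug one in. Bad-channel interpolation is
   likewise left as a hook.
2. **GFP peaks.** Global field power (GFP) is the per-sample population SD
   across channels; its strict local maxima (minimum separation 10 ms) are
   the moments of highest topographic signal-to-noise, and only the maps at
   those peaks enter clustering and back-fitting.
3. **Modified K-means.** Peak maps are clustered into k = 4 classes with a
   polarity-invariant K-means: assignment maximizes squared spatial
   correlation (Pearson, across channels of average-referenced maps) and the
   centroid update is the dominant eigenvector of the assigned maps'
   outer-product sum. 100 random restarts; the restart with the highest
   GFP²-weighted global explained variance (GEV) wins. Convergence: stable
   assignments or relative GEV change < 1e-6, at most 300 iterations. An
   empty cluster is re-seeded from the worst-fit map. Subject-level and
   group-level clustering use the same k and restart count; group templates
   come from re-clustering the pooled subject templates.
4. **Canonical labels.** Group templates are labeled A–D by exhaustively
   evaluating all 4! permutations against the canonical archetypes and
   taking the permutation with the largest total |spatial correlation|
   (ties broken lexicographically, logged).
5. **Back-fitting and metrics.** Each GFP peak is assigned the template with
   maximum |spatial correlation|; no temporal smoothing and no
   correlation-threshold rejection are applied by default (every peak is
   assigned, so coverages sum to exactly 100%; a threshold flag exists
   because published healthy-control coverages summing below 100 suggest
   some tools leave low-correlation time unassigned). Peak labels are
   expanded to continuous time by the nearest-peak (midpoint) rule, with the
   first/last cells extended outward by half the adjacent spacing. Maximal
   same-label runs are episodes, from which we compute per class: Coverage
   (% of analyzed time), Duration (mean episode length, ms), Occurrence
   (episodes/s), and the organizational transition matrix OrgTM_X→Y (% of
   all observed between-class transitions, summing to 100 over the 12
   ordered off-diagonal pairs). These definitions force the identity
   coverage/100 = occurrence × duration/1000 per class, which doubles as a
   run-time invariant. Whether published durations were computed from
   peak-expanded labels or a full-sample back-fit is not documented
   anywhere we know of; the nearest-peak convention is the standard
   peak-interpolation choice and is what we validate against ground truth.

## The synthetic generator

The generator emulates a 26-channel, eyes-closed resting recording
(10–20 montage, positions from MNE's standard layout): four archetype
topographies switched by a semi-Markov chain, riding a 10 Hz carrier
(eyes-closed alpha dominance) with additive spatially white sensor noise.

* **Ground truth.** Per-state mean dwell times and a row-stochastic,
  zero-diagonal conditional transition matrix. The defaults are calibrated
  to published group summaries of a chronic-insomnia cohort: dwell means
  from the group mean durations (healthy controls: 58.4/66.9/66.5/76.0 ms),
  transition rows from the row-normalized OrgTM percentages. Separate
  calibrations exist for healthy controls, patients before treatment, and
  patients after treatment. With episode-level stationary weights π and
  dwell means d, the implied metrics are Occurrence_X = π_X/Σπd,
  Coverage_X = 100·π_X d_X/Σπd, OrgTM_X→Y = 100·π_X P_XY; these closed
  forms are the test oracles, and they land within a few percent of the
  published occurrence/coverage values — evidence the calibration is
  self-consistent.
* **Dwell times and carrier alignment.** Dwells follow a gamma law
  (shape 2 — unimodal and positive, closer to empirical dwell histograms
  than a geometric law) quantized to a whole number of carrier half-cycles,
  so that topography switches fall at GFP minima. This quantization is the
  load-bearing realism choice: microstates are observable at GFP peaks in
  real EEG precisely because topography is quasi-stable across a GFP cycle
  and switches near its minima. A generator that switches at arbitrary
  phases hides ~17% of 70 ms dwells from the ~20 Hz peak sampling and
  biases recovered durations upward by ~30%; with arch-aligned switching
  the pipeline recovers durations and occurrences within a few percent.
  The quantization uses stochastic rounding with a floor of one arch, and
  the gamma mean is solved by a damped fixed point so realized dwells
  average the configured mean exactly. Dwell means must exceed one
  half-cycle (50 ms at the 10 Hz default); cohort jitter clamps at 1.05
  half-cycles.
* **Carrier and noise.** Each segment gets a log-normal amplitude
  (σ = 0.3) and a random polarity — the only phase freedom compatible with
  arch alignment, and unobservable anyway under polarity invariance. SNR is
  defined as RMS(signal)/RMS(noise) over the whole recording, noise white
  in space and time; the default snr = 2 yields a GFP peak rate of ~20/s.
  An optional mains sinusoid exists for notch-filter tests. Ocular/muscle
  artifacts and electrode drift are deliberately not modeled, so passing
  closure tests demonstrates correctness of the segmentation machinery on
  clean data, not robustness to real-world artifacts.
* **Cohorts.** Patients differ from controls only in dwell means and
  transition probabilities (group topographies did not differ in the
  calibration dataset). Responders are planted: their baseline truths are
  shifted along the reported predictor directions (longer Duration_A,
  shorter Duration_B, more D→B and C→B transitions; occurrence/coverage are
  emergent quantities and cannot be planted directly), and their
  post-treatment truths move to the post-treatment calibration while
  non-responders stay at their baseline truth. PSQI columns are constructed
  so that the responder rule (≥50% reduction; a strict > variant is a flag
  — both readings appear in the source literature, and on integer scores
  the printed 14/41 split is consistent with either) recovers the planted
  labels exactly. Other clinical scales get planted improvements matching
  the published pre/post means. Between-subject variation: log-normal dwell
  jitter (σ = 0.10) and Gaussian transition-logit jitter (σ = 0.15),
  yielding feature SDs comparable to the published tables; baseline
  features in the cohort table are the closed-form metrics of each
  subject's individual truth plus small measurement noise.

## Group statistics

Normality is gated per variable by Shapiro–Wilk at α = 0.05: normal →
t-tests, mean ± SD summaries; non-normal → Wilcoxon/Mann–Whitney, median
(IQR). Bonferroni adjustment is applied with an explicit family size that is
always emitted (transition tests use family 12). The mixed two-way ANOVA
(group between × class within) is delegated to pingouin; no sphericity
correction is applied by default (switchable), matching the source
analysis's silence on the issue. A rank-based Dunn procedure is available as
an alternative post-hoc backend; pairing "Dunn's test" with a
repeated-measures ANOVA is nonstandard, so the default post-hoc backend is
the gated parametric/rank family.

TANOVA: the topographic permutation test's statistic is 1 − |Pearson r|
between unit-norm group-mean maps (global map dissimilarity; mean pairwise
for >2 groups), with p = (1 + #{null ≥ observed})/(1 + n_perm). Because
subject maps from polarity-invariant clustering carry arbitrary signs, all
maps are sign-aligned once to the pooled first principal component before
the test — a permutation-invariant alignment. Aligning within groups
instead destabilizes the permutation null (a permuted half-and-half group
can align to either orientation, fattening the null's tail and destroying
power); the global alignment keeps the test exact and calibrated, which the
test suite verifies by nested simulation.

## Response prediction

Responder labeling, minority-class bootstrap oversampling (duplicated rows
carry a provenance mark), and multi-stage feature selection over the
24-name microstate feature vocabulary:

1. three rankers nominate their top-15: random forest (Gini importance),
   RFE with L2 logistic regression on standardized features (drop the
   smallest-|coefficient| feature one at a time), gradient-boosted trees
   (gain importance);
2. stability: 100 subject bootstraps per ranker, keep features nominated in
   >75% of resamples;
3. consensus: by default the features stable under **all three** rankers.
   The source describes both an at-least-two rule and an all-three
   intersection; empirically the boosting ranker is nearly non-selective on
   n≈54 tables (it spreads gain over most features, so ~13 of 28 features
   are "stable" for it), and a two-method rule then admits chance-correlated
   noise via boosting plus any one other method. The all-three intersection
   is what makes the stage selective; `min_methods=2` is available.
   Stage order (stability before or after consensus) is configuration, not
   inference.
4. collinearity pruning: iteratively drop the largest-VIF feature while any
   VIF = 1/(1−R²) exceeds 10 (perfect collinearity reports ∞), then for any
   pair with |Pearson r| > 0.8 drop the member with the larger mean |r|;
   every removal is logged with its evidence.

Model zoo: CatBoost, XGBoost, logistic regression, calibrated-probability
SVM, random forest, k-NN (5 neighbours), Gaussian naive Bayes, AdaBoost —
100 trees/iterations where applicable, random_state 42, library defaults
otherwise. The registry is config-driven: a backend that is not installed
is skipped with a warning and marked absent in the report rather than
failing the run. Evaluation repeats a stratified 75/25 shuffle split 100
times and reports mean ± SD of AUC, accuracy, precision, recall, F1 and
PR-AUC, with percentile ROC bands over the repetitions. **Oversampling
placement matters:** balancing before splitting leaks duplicated subjects
across folds and inflates apparent performance; the default here balances
inside the training fold only, and the pre-split order is available behind
a `pre_split_oversample` flag whose report is explicitly marked optimistic. DeLong's
test compares correlated AUCs via placement-value structural components
(identical orderings degrade to p = 1 with a warning). SHAP attribution is
delegated to the shap library when present; otherwise the report section is
omitted with a warning — the contract (per-subject signed values,
additivity to the model output, ranking by mean |value| with dominant sign)
is what the package specifies and tests.

A note on calibration claims: with n≈54 subjects, a single null feature
table carries real in-table chance correlations, so its evaluated "null"
AUC scatters around 0.5 with SD ≈ 0.065 across tables. Calibration
statements (null AUC ≈ 0.5, leakage-guard bounds) therefore refer to
averages over generated tables, and the tests average accordingly.

## Problem sizes used in tests

The test suite validates closure at the study scale it emulates — 20
subjects × 150 s × 26 channels at 256 Hz, snr 2, 70 ms dwells, 100 K-means
restarts — and selection recovery over 20 seeded repeats of 54-subject
tables with 100-fold bootstrap stability; statistical calibration uses 200
nested repeats with 199 permutations. Smaller configurations (4 subjects,
60 s, 20 restarts) back the faster unit-level closure checks.

## Known limitations

* The generator's single-carrier, white-noise signal model omits 1/f
  background, spatially correlated noise, artifacts, and eyes-open/closed
  block structure (it emits one continuous eyes-closed record); closure
  results bound algorithmic error, not robustness on real recordings.
* Dwell quantization to carrier half-cycles discretizes the dwell
  distribution (multiples of 50 ms at the default carrier); means are
  calibrated exactly but higher dwell moments are distorted, and dwell
  means within ~5% of one half-cycle degenerate toward single-arch
  segments.
* Occurrence and coverage responder effects cannot be planted
  independently of dwell/transition effects.
* The prediction stage inherits the small-n instability it measures:
  per-table chance structure dominates single-table results, which is why
  all its guarantees are stated over repeated seeded tables.
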