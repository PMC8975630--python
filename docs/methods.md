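# Methods

`neurofuse` implements a multimodal classification pipeline that separates
children with autism spectrum disorder (ASD) from typically developing (TD)
children using three concurrently recorded modalities — eye fixation,
facial expression and EEG — fused in two levels and evaluated with
leave-one-out cross-validation (LOOCV). The study cohort such pipelines are
run on is clinical and not distributable, so the package ships a synthetic
cohort generator that reproduces the statistical structure the method
exploits; all tests and the acceptance script run end-to-end on generated
cohorts.

## Feature extraction

### Eye fixation (gaze module)

Fixation points of all training subjects are pooled and clustered into K
areas of interest (AOIs) with Lloyd's K-means, written out explicitly:
nearest-center assignment (ties to the lowest cluster index) alternating
with centroid updates of the within-cluster sum of squares
`J = Σ_n Σ_k r_nk ||x_n − μ_k||²`, until the maximum center shift drops
below `tol` (default 1e-6 px) or `max_iter` (100) is reached. Seeding is
k-means++-style with `n_init` (default 10) restarts, keeping the run with
the lowest J; an emptied cluster is reseeded at the point farthest from its
assigned center. J is non-increasing across iterations within a run, which
the tests assert.

A subject's feature vector is the fraction of their fixations assigned to
each fitted AOI — a length-K probability vector ("distribution
frequency"). K is a free parameter; 8, 12, 16 and 20 are the values worth
scanning, and 8 is the default. Inside cross-validation the clustering is
refit per fold on training fixations only and held-out subjects are
projected onto the trained centers.

### Facial expression (expr module)

The pipeline consumes one categorical expression label per video frame
(produced upstream by any facial-expression-recognition system; a
pluggable labeler hook is provided, and the synthetic generator produces
labels directly). The feature vector counts, in each consecutive window of
40 frames, how many frames show the stimulus's target expression. A
trailing partial window is dropped so every count lives on the common
[0, 40] scale; tracks of unequal length are truncated to the shortest
full-window length with a warning. At the default 25 fps and 40 s stimulus
this yields 25 windows.

### EEG (eeg module)

Recordings use the 14-channel Emotiv EPOC montage (AF3, F7, F3, FC5, T7,
P7, O1, O2, P8, T8, FC6, F4, F8, AF4; 10–20 placement). The pipeline:

1. **Band-pass filter** 0.2–45 Hz, zero-phase Butterworth of order 6
   (forward–backward, i.e. an effective 12th-order magnitude response).
   Order 6 is the lowest for which a 50 Hz mains tone is attenuated below
   10% amplitude while the passband stays flat to within 5%.
2. **Epoching and artifact rejection**: consecutive non-overlapping 2 s
   epochs; an epoch is dropped when any channel exceeds 100 µV peak
   absolute amplitude (blinks, movement, muscle). Both parameters are
   configurable; a recording with no surviving epoch is an error.
3. **Band power**: per epoch and channel, a Hann-windowed periodogram
   summed over the bins of each band — theta [4, 6), alpha [6, 13),
   low beta [13, 20), high beta [20, 30), gamma [30, 45) Hz. The
   intervals are half-open so adjacent bands never double-count an edge
   bin. These band edges (no delta band, theta capped at 6 Hz) are the
   pipeline's fixed convention and are deliberately not "corrected".
4. **Region aggregation**: mean over epochs and over the channels of six
   scalp regions — LF = {AF3, F3, F7, FC5}, RF = {AF4, F4, F8, FC6},
   LT = {T7}, RT = {T8}, P = {P7, P8}, O = {O1, O2} — giving a 6 × 5
   power table per subject.

**Feature screening.** For each of the 30 region × band features, Levene's
test (classic, mean-centered) compares group variances; Welch's t is used
when it rejects at 0.05, the pooled-variance Student t otherwise; features
with two-sided p < α (default 0.05) are retained. The t-test operates on
per-subject averages, not epochs, matching the subjects-as-replicates
design. Besides the data-driven `screened` mode there is a `fixed12` mode
returning the canonical 12-feature panel (theta in LF/RF/RT/P/O, alpha in
P/O, low beta in LF/RF/P/O, gamma in LF) in that order; `fixed12` is the
default because it is deterministic and label-free.

## Fusion and classification

**Level 1 (feature fusion).** The expression and gaze vectors are
concatenated into one behavioral vector and classified by a base
classifier, producing subdecision d2; the EEG vector is classified
independently, producing d1. Base classifiers: random forest (500 trees),
RBF SVM (C = 1) and K-nearest-neighbour (k = 5), the latter two behind a
standardisation step. All hyperparameters sit in `FusionConfig`.

**Level 2 (decision fusion).** The pair (d1, d2) is fused by an
attribute-weighted naive Bayes over categorical attributes. With n(m)
attributes, raw counts n(d_m=v) and n(d_m=v ∧ c):

    W(d_m=v | c) = [ n(m) + n(d_m=v ∧ c) / n(d_m=v) ] / n(m)

(W = 1 when the value is unseen), so every weight lies in
[1, (n(m)+1)/n(m)] and reduces to 1 for uninformative values. The class
score is `P(c) · Π_j P(d_j|c) · W(d_j|c)`, normalised over classes and
computed in log space. Conditionals use Laplace smoothing (λ = 1); the
weights use raw counts because the additive n(m) term already guards
zeros. Exact posterior ties go to the larger prior, then to ASD (canonical
class order). Forcing all weights to 1 reproduces standard naive Bayes
exactly, which the tests use as a reduction check against an independent
enumeration oracle.

## Leave-one-out evaluation

`loocv()` runs n folds, one held-out subject each. Per fold, everything
that can see labels or pooled data — gaze K-means, the EEG screen (in
`screened` mode), base classifiers, the naive-Bayes table and weights — is
fitted on the n−1 training subjects only. The decision table that trains
the weighted naive Bayes is built from **inner** leave-one-out
subdecisions over the training fold: each training subject is predicted by
branch classifiers fitted on the fold minus that subject. Resubstitution
subdecisions would be near-perfect and would drive the learned weights
toward degenerate confidence, so the inner loop is the default and only
behaviour. Two deliberate simplifications inside the inner loop: gaze
features reuse the outer fold's K-means (the clustering is label-free),
and the feature standardisation for SVM/KNN uses the training fold's
statistics. Neither touches the outer held-out subject; the test suite
verifies that corrupting a held-out subject's label never changes that
subject's own prediction.

Reports carry per-subject held-out predictions, accuracy, a
column-normalised confusion matrix (entry (i, j) = % of true-class-j
subjects predicted as class i; columns sum to 100), and the off-diagonal
"confusion graph" edges used to compare which class each modality
confuses. For hybrid runs the held-out branch subdecisions are kept too —
they are themselves valid single-branch LOOCV predictions, which is how
branch accuracies are obtained without extra passes.

## Synthetic cohorts

`CohortSpec`/`generate_cohort` produce labelled cohorts, 40 + 40 subjects
by default, all randomness flowing from one integer seed (identical specs
give byte-identical cohorts):

- **Gaze**: a 2-D Gaussian mixture (sd 60 px) over eight AOI centers on a
  1920 × 1080 screen, four "social" (face region) and four peripheral
  "nonsocial"; a subject's social mixture weight is a clipped Gaussian
  around the group bias (TD 0.58 ± 0.05, ASD 0.42 ± 0.14); 120 fixations
  per subject.
- **Expression**: 1000 frames (25 fps × 40 s); each frame shows the target
  expression with the subject's probability (TD 0.30 ± 0.04, ASD
  0.22 ± 0.10), otherwise a uniformly drawn non-target label.
- **EEG**: 40 s at 128 Hz; each channel is the sum over the five bands of
  unit-RMS band-limited noise (white noise band-pass filtered), scaled by
  the band's base amplitude (theta 2.0, alpha 2.5, low beta 1.0, high beta
  0.75, gamma 0.5 µV RMS) and a per-subject, per-band log-normal factor
  (σ = 0.20 for ASD, 0.50 for TD), plus broadband sensor noise
  (σ = 0.5 µV). For ASD subjects the theta component of the channels in
  LF, RF, RT, P and O is multiplied by `theta_gain_asd` (default 2).

The variability is drawn per band rather than as one broadband scalar: a
global gain is linearly separable from band-specific elevation and does
not reproduce the asymmetric error structure seen in practice, whereas
band-specific variability does (and is the physiologically plausible
model of inter-individual band-power differences).

The default effect sizes are free parameters of the emulation — nothing
pins them to any real cohort. They were chosen so that each single
modality's LOOCV operating point is realistic for this problem class:
EEG recognising ASD more reliably than TD (roughly 90% vs 80%), the
behavioral modalities the reverse, and overall single-modality accuracies
in the low-to-mid 80s. `CohortSpec.null()` strips every group difference
(equal biases, probabilities and heterogeneity, theta gain 1), which is
the configuration used for calibration checks.

**What the generator does not emulate:** saccade dynamics and fixation
durations, facial video (the pipeline starts at frame labels), EEG
waveform realism (1/f background, volume conduction, channel
correlations), artifacts with real morphology, and any age or severity
structure. Passing tests therefore demonstrate that the pipeline recovers
planted statistical structure without leakage — not clinical performance
on real children.

## Numerical and design choices

- K-means ties go to the lowest cluster index; restarts share one seeded
  generator; loss comparisons across restarts are exact float comparisons.
- After Lloyd converges, a Hartigan-style polish greedily applies single-
  point cluster moves that strictly lower J (the move criterion accounts
  for the centroid shift: removal gain n/(n−1)·d² versus insertion cost
  m/(m+1)·d²), then lets Lloyd settle again.  Lloyd fixed points are not
  always single-move optimal; the polish recovers the exhaustive optimum
  on small instances in every test and only ever lowers J.  Singleton
  clusters are never emptied; moves are capped at 100 per round.
- Degenerate t-test input (zero variance in both groups, equal means)
  returns t = 0, p = 1 rather than NaN.
- If the screen selects nothing, `screened` mode falls back to all 30
  features instead of emitting an empty matrix.
- Unseen attribute values at prediction time get the smoothed zero-count
  conditional over an enlarged value domain and weight 1.
- Per-fold classifier seeds are derived deterministically from the config
  seed and fold index, so a fixed seed reproduces an entire evaluation
  report byte-for-byte.
- The LOOCV harness precomputes per-subject expression features and EEG
  region × band tables once (they are label-free) and refits everything
  label-dependent per fold.

## Problem sizes used by the test suite and acceptance script

The calibration test uses 200 null cohorts and 20 planted-effect cohorts
at n = 20 + 20 with the default 40 s EEG; the pipeline-integrity test uses
the default 80-subject cohort with the KNN base classifier; the
complementarity test uses 20 cohorts of n = 30 + 30 with an explicitly
complementary configuration (EEG branch near-ceiling on ASD and weak on
TD via `eeg_subject_sd` 0.06/0.8 and theta gain 1.6; behavioral branch
mildly TD-leaning) and the SVM base classifier. The acceptance script runs
every modality × classifier combination plus hybrid fusion with the SVM
and KNN base classifiers on one default 80-subject cohort; the hybrid
random-forest combination is omitted because the inner leave-one-out
multiplies the number of forest fits by the cohort size, for no additional
insight over the two other classifiers.

## Known limitations

- Two-attribute decision fusion can at best resolve disagreements between
  its branches; when one branch dominates the other by a wide margin the
  fused decision collapses onto the dominant branch, and the population-
  level gain under opposite class asymmetries is bounded (a few points).
- The weighted naive Bayes assumes conditionally independent subdecisions
  given the class; branch errors correlated through a shared latent trait
  violate this and shrink the fusion gain.
- Feature screening at α = 0.05 without multiplicity correction is part of
  the pipeline's design (the fixed 12-feature panel plays that role);
  the screened mode inherits the usual selection noise at small n.
- LOOCV accuracy on n = 80 has a standard error of several points; single-
  seed accuracies should be read accordingly.
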