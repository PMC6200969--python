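# Methods

`emorsa` implements a complete multivoxel-pattern analysis chain for
testing whether a brain region represents emotion categories *abstractly*
— that is, whether the activity pattern evoked by an emotion (happy,
angry, fearful) generalizes across the visual stimulus type conveying it
(face, body, whole person).  Because no public dataset accompanies this
design, the package ships a synthetic-cohort generator with planted,
parameterized ground truth, so every stage of the chain is testable and
its calibration measurable.

## The design and its condition space

The experimental design crossed 3 emotions with 3 stimulus types, giving
9 conditions.  Everywhere in the package conditions are ordered
emotion-major: `happy_face, happy_body, happy_whole_person, angry_face,
…, fearful_whole_person`.  A cohort has 20 subjects by default, each with
3 runs; each run presents 2 blocks of each condition (18 blocks), blocks
of 20 s separated by 10 s fixation, TR 2 s.

## Generative model of the synthetic cohorts

The abstract-representation hypothesis states that within-emotion
patterns are correlated across stimulus types while between-emotion
patterns are not.  The generator realizes this with the minimal two-
component model.  Inside a planted spherical region, the noiseless beta
of condition (emotion *e*, type *t*) at voxel *v* is

    a · ( λ s_e[v] + (1 − λ) u_{e,t}[v] )

with amplitude *a*, share fraction λ ∈ [0, 1], an emotion-shared
standard-normal field `s_e` and a condition-private field `u_{e,t}`, both
drawn once per subject.  Per-run betas add white Gaussian noise of sd σ
(`noise_sd`); outside planted regions betas are pure noise.  The expected
within-emotion cross-type correlation in planted voxels is

    λ²a² / (λ²a² + (1 − λ)²a² + σ²),

verified by simulation in the test suite.  λ = 0 is the null for the
hypothesis (types share nothing); λ = 1 with no noise makes the patterns
identical across types.  `generate_null` produces i.i.d. Gaussian betas
with no structure at all and is the calibration input.

Time-series mode convolves per-run condition boxcars with a canonical
double-gamma HRF (response peak 6 s, undershoot 16 s, amplitude ratio 6,
peak-normalized), multiplies by the run's betas, and adds a nuisance
contribution (6 random-walk motion-like regressors and 2 white
tissue-like regressors, with per-voxel weights of sd `nuisance_sd`,
default 0.5) plus white scanner noise (`scan_noise_sd`, default 1).  The
noise is white by construction — no AR(1), physiological noise, head
motion, or spatial autocorrelation is simulated — so passing tests
demonstrate correctness of the estimators and calibration under ideal
noise, not robustness to real-fMRI artifacts.  Block allocation within a
run is a seeded shuffle (counterbalancing of the original experiment is
unknowable).  All randomness descends from `SeedSequence([seed, stream])`
with one child per subject and a fixed draw order, so identical specs
reproduce bit-identical data.

## GLM pattern extraction

One GLM per run: 9 condition regressors (boxcar × HRF), nuisance columns
plus their first temporal differences, and an intercept; per-voxel OLS;
nuisance betas discarded.  This yields 3 exemplars per condition (one per
run) for the classifier stage; the RSA stage uses the run-averaged
pattern.  Fixation and response periods are left unmodeled (implicit
baseline), there is no high-pass filter or prewhitening (the synthetic
noise is white), and betas enter RSA raw — unscaled and not mean-centered.
Rank-deficient designs are rejected with the collinear columns named.

## Representational similarity analysis

The neural RDM of a voxel set is the 9 × 9 matrix of correlation
distances (1 − Pearson r) between condition patterns; its diagonal is
undefined (NaN) and excluded everywhere.  The abstract-emotion model RDM
is 0 for same-emotion pairs and 1 otherwise.  Agreement is Kendall's
tau-a over the 36 upper-triangle entries:

    τ_a = (concordant − discordant) / (n(n−1)/2),

with tied pairs counting only in the denominator.  The tie-inclusive
denominator matters: against a binary model RDM, 378 of the 630 entry
pairs are tied in the model, so τ_a saturates at 243/630 ≈ 0.386 (all 9
within-emotion entries below all 27 between-emotion entries), never at 1.
A tie-corrected variant (tau-b) would change every value, which is why
the statistic is implemented here rather than taken from
`scipy.stats.kendalltau`.

The searchlight evaluates this statistic for every voxel over the
surrounding sphere of 9 mm radius (123 voxel offsets at 3-mm isotropic
voxels), assigning the tau to the center voxel.  Spheres clipped by the
mask contribute if at least `min_voxels_per_sphere` (default 10) in-mask
voxels remain; smaller spheres yield NaN and a logged count.  The
implementation computes per-sphere sums, squared sums and cross-products
by 3-D convolution with the spherical kernel, and reduces tau-a against
the binary model to a vectorized count over the 9 × 27
within/between-entry pairs; a naive per-voxel loop reproduces it to
1e-12 in the tests.

## Group inference

Per voxel, subjects' tau values enter a one-sided (positive) Wilcoxon
signed-rank test.  For n ≤ 25 the p-value is exact: the full distribution
of the positive-rank sum over all 2ⁿ sign assignments, computed by a
generating-function convolution, with zeros dropped and midranks for ties
(ties across subjects are common because tau-a is discrete: odd
sign-sums over 243 pairs divided by 630).  Above n = 25 a normal
approximation with tie correction and continuity correction is used.
The map is thresholded at p < α (default 0.01) and connected components
(26-connectivity by default; 6 and 18 available) of at least
`min_cluster_size` voxels (default 30) are reported with their size, peak
(largest across-subject summed tau; ties broken by scan order) and peak
world coordinates via the NIfTI affine.  No correction beyond the
cluster-extent rule is applied — uncorrected by design, matching the
procedure it implements.

A measured property worth knowing: on null cohorts (20 subjects, 24³
grid) the voxelwise rejection fraction at p < 0.01 is well calibrated
(≈ 0.009), but the tau maps are heavily smoothed by sphere overlap, so
suprathreshold voxels arrive in sphere-sized blobs and the uncorrected
extent rule admits ≈ 0.5 false clusters per cohort (P(zero) ≈ 0.65).
This is precisely why the MVPA confirmation step below exists: in the
same simulations, false clusters are essentially never confirmed.

## Cross-modal MVPA confirmation

For each cluster, per subject and stimulus-type pair, an L2-regularized
logistic classifier (C = 1; per-feature standardization fit on the
training fold only) is trained on one type's 9 samples (3 runs × 3
emotions) and tested on the other type's, and the two folds are averaged.
Schemes: three-way emotion classification (chance 1/3) and valence —
happy vs angry+fearful — where half of the angry and half of the fearful
samples are dropped at random (odd halves rounded up in one emotion and
down in the other, direction random) in both folds so classes stay 1:1
(chance 1/2), repeated over 20 seeded subsamplings and averaged.  Group
inference is a two-tailed one-sample t test of the per-subject pair
accuracies against chance; "significant" additionally requires the mean
to exceed chance.  A zero-variance accuracy vector is degenerate: exactly
at chance it is maximally null (t = 0, p = 1); constant strictly above
chance (every subject perfect, common on strongly planted synthetic
clusters) is taken as significant, the t → ∞ limit.  A cluster is
*confirmed* when at least one scheme is significant for at least two of
the three type pairs; clusters failing both schemes on all pairs are
excluded.

## Univariate follow-up

Cluster-mean betas (runs averaged, then voxels) per condition feed a
3 × 3 fully within-subject ANOVA (statsmodels `AnovaRM`; uncorrected df —
(2, 38) and (4, 76) at n = 20; Greenhouse–Geisser is deliberately not
applied) and a within/between contrast: after subtracting each stimulus
type's mean response, the mean |difference| over the 9 same-emotion
cross-type condition pairs is compared to that over the 18
different-emotion cross-type pairs with a paired t test.  "Different
emotions" is read as cross-type pairs only, mirroring the within-emotion
comparison; the per-type subtraction makes both quantities exactly
invariant to any per-type constant.

## Stimulus motion scoring

Video clips (grayscale 0–255, 25 frames/s) are scored by adjacent-frame
absolute luminance change: per frame pair, the mean change over pixels
exceeding a noise threshold (default 10, the camera noise floor; 0 if no
pixel exceeds it), then the mean over frame pairs.  The alternative
reading — thresholded change averaged over *all* pixels — is exposed as
`mean_over_all_pixels`.  Emotion groups of paired videos are compared
with paired t tests.

## Numerical and design choices

- Exact Wilcoxon survival functions are cached per rank multiset, making
  whole-brain group maps cheap (most voxels share a tie pattern).
- Correlations are clipped to [−1, 1] before distances; constant patterns
  raise an error at the API level and yield NaN inside the searchlight.
- The searchlight's convolutional moving sums match the naive loop to
  float rounding; tau values are exact counts, so agreement is exact
  unless two dissimilarities collide within ≈ 1e-13 (probability
  negligible for continuous data).
- Degenerate t inputs: zero variance at the null value gives t = 0,
  p = 1; off the null value, t = ±∞ with NaN p, flagged `degenerate`.
- Reference simulation sizes: calibration and recovery studies use 24³
  grids with 20 subjects and 10 seeds, and chance-level studies 200
  simulated subjects with a 40-voxel cluster — large enough for the
  Monte-Carlo error bands asserted in the tests.

## Known limitations

- White noise only; no spatial autocorrelation, motion or physiology —
  calibration results do not transfer verbatim to real fMRI noise.
- No multiple-comparison correction beyond cluster extent; the measured
  false-cluster rate above quantifies the consequence.
- No anatomical labeling, template registration, alternative RDM
  distances, or searchlight MVPA.
- The classifier sees 9 training samples; conclusions about classifier
  choice beyond regularized logistic regression are out of scope.
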