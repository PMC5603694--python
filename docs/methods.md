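# Methods

`affectmvpc` implements a multivoxel pattern classification (MVPC)
analysis of dimensional affect: given per-stimulus brain activation maps
("brain states") and 9-point normative valence/arousal ratings, it asks
how well a linear decoder trained on other subjects predicts the
binarized affect class of a held-out subject's brain states, where in
the brain the decodable signal lives, and where in valence–arousal space
the decoder fails.

## The decoding model

Each brain state is a voxel vector `x ∈ R^d` (gray-matter masked).
Ratings are binarized at the scale midpoint: positive valence `V_pos`
iff `V ≥ 5.0`, high arousal `A_high` iff `A ≥ 5.0` (boundary
inclusive).  The classifier is a soft-margin linear SVM
(`min ½‖w‖² + C Σ ξ_i`, C = 1, no feature standardization); the signed
hyperplane distance `(w·x + b)/‖w‖` carries the predicted class in its
sign.  Exact ties predict the positive class; a constant-feature
(degenerate) training pool scores 0.5 by convention.

### Class-balanced rotation cross-validation

Binarized labels are generally imbalanced.  For each test subject the
larger class (`N_max` stimuli) becomes the *rotate set*, the smaller
(`N_min`) the *static set*.  For each of `N_max` rotations, a circular
window of `N_min` consecutive rotate-set stimuli (ordered by stimulus
id, shifted one position per rotation) joins the full static set, so
every test pool holds exactly `N_min` stimuli per class and every
majority stimulus is tested at least once.  Balanced classes collapse to
a single rotation.

*Inter-subject LOOCV*: each subject is held out in turn; the SVM is
trained on the other `N_subj − 1` subjects and evaluated on the held-out
subject's rotation pools; the `N_max` rotation accuracies average into
one per-subject accuracy.  Each training subject contributes its own
class-balanced selection at the same rotation shift (taken modulo its
own `N_max`).  When a training subject viewed the same counterbalanced
stimulus set as the test subject this *is* the corresponding-stimulus
extraction; when it viewed the other set it yields class-matched
counterparts of the same size — the only consistent reading when half
the sample saw disjoint stimuli.

*Intra-subject LOOCV*: within each rotation pool, stimulus-wise
leave-one-out inside the single subject; the remaining pool is used as
is (unbalanced by the single removed item).

The feature mask for each fold is the leave-one-out group gray-matter
mask built from the training subjects only (majority vote with inclusive
threshold 0.5), optionally intersected with an ROI mask.  Group
performance is summarized by the mean per-subject accuracy, its
t-based 95% CI, a two-tailed one-sample t-test against chance 0.50, and
TPR/FPR (positive class `V_pos`/`A_high`) pooled over folds within
subject and averaged over subjects.  Head-coil- or sex-type group
contrasts use Welch's two-sample t-test.

### Numerical implementation

The engine precomputes the linear Gram matrix of the masked features
once per fold and fits the SVM on kernel sub-blocks; this is
mathematically identical to the primal fit (asserted in tests to 1e-4)
and removes the dominant cost of the ~775 classifier fits per
simulated dataset.  The SMO stopping tolerance is 1e-2; against 1e-3
per-subject accuracies change by ≤ 0.003 on null data, far below the
across-subject spread.

## Univariate pipeline

- **GLM**: OLS with two condition regressors (e.g. `V_pos`, `V_neg`)
  built from boxcars convolved with the canonical double-gamma HRF
  (6 s peak, 16 s undershoot, 1:6 ratio) plus Legendre drift up to
  order 2 (`drift_order=None` fits no drift, used when exact algebraic
  identities are wanted).  The contrast is `V_pos − V_neg` /
  `A_high − A_low`.
- **Beta series (LSS)**: per-trial betas by least-squares-separate — one
  regressor for the target trial, one summing all others, plus drift.
  With trial onsets ≥ ~35 s apart (the HRF support is 32 s) and no
  shared drift columns, LSS equals trial-wise projection exactly.
- **Group maps**: voxelwise one-sample t across subjects, `df = n − 1`;
  zero-variance voxels are flagged, not ±∞.  The two-tailed critical
  value at `p ≤ 0.001`, `df = 31` is 3.63.
- **Cluster-extent correction**: Monte-Carlo simulation of smooth
  Gaussian null fields inside the analysis mask (smoothness summarized
  by one Gaussian FWHM, default 6 mm, matched to the generator's
  smoothing), two-sided voxel thresholding, face-connected (NN = 1)
  components clustered per sign, maximum component size recorded per
  iteration; `k_min` is the (1 − α) quantile with linear interpolation,
  hence possibly fractional; survival means `size ≥ ⌈k_min⌉`.  Clusters
  report size, sign, mean |t|, and center of mass in mm through the
  NIfTI affine (unweighted member mean).
- **Relaxed masks**: morphological dilation (face-connected element,
  1 or 2 passes, re-intersected with the group GM mask) or relaxed
  voxelwise thresholds (`p ≤ 0.01`, `p ≤ 0.05`) with their own
  Monte-Carlo `k_min`.

## Cluster stability

Leave-one-out cluster maps are matched to the group map greedily:
cross-validated clusters in descending size order each claim the nearest
(center-of-mass Euclidean distance) unclaimed group cluster; each group
cluster is matched at most once per subject; no distance cap is applied.
Size ties break by larger mean |t| then lower cluster id; distance ties
by lower group cluster id (the original procedure specifies neither, so
deterministic rules keep runs reproducible; the Hungarian optimum is
deliberately *not* used — the greedy order-dependence is part of the
procedure).  Summaries report, per group cluster, the fraction of
subjects matched and mean/sd of matched size and distance over matched
subjects only.

## Decoder interpretation

- **Encoding patterns**: a linear decoder's weights are filters, not
  activations; the equivalent forward pattern is
  `a = Cov(X_train) · w`, rescaled to unit maximum absolute intensity
  (maps are reported as fractions of `VI_max`).  On whitened features
  this is the identity on `w`.
- **Affect-space projection**: per-stimulus signed distances averaged
  over all cross-validation folds; a maximum-margin line in (V, A)
  coordinates is fitted to the distance *signs* and compared with the
  ideal boundary (`V = 5` or `A = 5`).  Rendering metadata (half-plane
  sign, saturation = min(|d|, 1)) is emitted for plotting.
- **Joint misclassification surface**: per stimulus, misclassification
  rates are averaged across subjects independently for valence and
  arousal and multiplied (`p_joint = p_V · p_A`; chance
  0.5 × 0.5 = 0.25).  The phrase "misclassification accuracy" is read as
  the error rate; the correct-rate product shares the 0.25 null and is
  also computed (`mode="correct"`).  Subjects in whose test rotations a
  stimulus never appeared contribute nothing for that stimulus.
  Probabilities are clipped to [1e-6, 1 − 1e-6] and warped with
  `y = atanh(2p − 1)`; a Gaussian process (squared-exponential kernel
  with fitted amplitude and per-axis length scales, white-noise floor
  1e-4, constant mean via target normalization, marginal-likelihood
  optimization) regresses `y` on (V, A); predictions over the grid
  V ∈ [1.0, 9.0] × A ∈ [2.0, 7.5] are back-transformed with
  `p = (tanh(y) + 1)/2`, guaranteeing surface values in [0, 1].
  Duplicate coordinates are jittered by 1e-6 rating units (seeded).

## Label scaling

Independent 5-point ratings map to the 9-point normative scale by IRLS
linear regression with Tukey bisquare weights (tuning constant 4.685,
intercept included, coefficient-convergence 1e-8, ≤ 50 iterations),
fitted on stimuli rated on both scales; the Spearman ρ between fitted
and observed 9-point ratings is reported on the training pairs (the
held-out variant is a caller choice — both are trivially available from
the returned model).

## Synthetic data generator

The generator defines the study conditions for every test:

- **Stimuli**: `n` images in positive/neutral/negative valence tiers
  (uniform within the thirds of [1, 9]); arousal uniform on [2.0, 7.5]
  with an optional valence correlation parameter (default 0 — how the
  original stimulus set balanced arousal across tiers is unknown, so it
  is exposed, not fixed).  5-point ratings are the exact linear rescale
  of the 9-point ratings passed through a configurable latent linear
  bias plus Gaussian noise (sd 0.25), clipped to [1, 5].  Stimuli split
  into two counterbalanced sets A/B with equal tier composition;
  odd-numbered subjects view set A, even view B.
- **Brain states**: `β[s,i] = snr·(w_V·g(V_i) + w_A·g(A_i)) +
  offset_s + noise`, with `g(r) = (r − 5)/4` so the class threshold is
  the signal zero, per-subject smooth offset maps (sd 0.3), and
  unit-variance Gaussian noise smoothed to 6 mm FWHM (matching the
  nominal preprocessing kernel; the smoothing is what gives the
  cluster-size simulation something to correct for).  Planted weight
  maps live on disjoint spherical blob supports (~10% of the grid each)
  so contiguous clusters exist and genuinely signal-free voxels remain.
- **Timeseries** (for LSS validation): 2.5 s events, uniform 2–6 s
  jittered ITIs, TR 2 s, amplitudes convolved with the double-gamma HRF,
  optional Legendre drift and Gaussian noise.
- **GM masks**: a smooth-field template covering 75% of the grid with
  independent per-subject voxel flips (rate 0.05).

Default problem sizes are desk scale: 12×12×12 voxel grid (1728 voxels,
3 mm isotropic), 16 subjects, 88 stimuli with 44 per subject — the
stimulus-per-subject count of the emulated design with half the subject
count and ~5% of the voxel count, chosen so a full 20-seed null
calibration completes in minutes.  What passing tests show is that the
*procedures* are correct and calibrated (chance at 0.50/0.25, planted
signal recovered, leakage-free folds); they do not show that real fMRI
noise (physiological structure, motion residuals, inter-subject
anatomical misalignment) is captured — the generator's noise is
stationary, Gaussian, and anatomically unstructured by design.

## Known limitations

- The group one-sample t-test treats per-subject LOOCV accuracies as
  independent, but each subject's brain states are reused as training
  data in every other fold, which makes the accuracies positively
  dependent and the test mildly anticonservative on null data (its
  false-positive rate runs above the nominal level; the mean accuracy
  itself is unbiased at 0.50).  This is a property of the
  leave-one-subject-out procedure, not of the implementation.
- OLS stands in for temporally-whitened (REML) GLM estimation; no
  temporal autocorrelation is modelled in generation or fitting.
- Spatial smoothness is a single Gaussian FWHM, not a mixed
  autocorrelation-function model; at desk scale this preserves the
  logic, not the numerics, of cluster-size simulation.
- Whether the original two-sided clustering merged opposite-sign
  adjacent voxels is unknown; sign-pure clustering is implemented.
- The rotation scheme's ordering ("first N_min stimuli") is realized as
  id-ordered circular shifts; disjoint-block schemes would test fewer
  pools.
- No nonlinear kernels, no hyperparameter search, no voxel-stability
  feature selection: whole-mask features are the point of the analysis.
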