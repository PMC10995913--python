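# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limitations of `normdev`, in enough detail
to reason about what its tests do and do not establish.

## Normative model

Each of the 169 regional measures (148 Destrieux cortical thicknesses in
mm, 21 aseg subcortical volumes in mm³) is modelled independently on
healthy reference controls. The raw response is standardized by the
reference mean and SD, passed through the two-parameter sinh-arcsinh warp

    φ(y) = sinh(δ · asinh(y) − ε),      δ > 0,

and the warped response is given a Gaussian Bayesian linear regression
with an isotropic zero-mean prior on the weights (precision α) and noise
precision β. The warp is strictly increasing for any δ > 0 (its
derivative δ·cosh(δ·asinh y − ε)/√(1+y²) is positive), so it is a valid
change of variables; ε skews the implied response distribution and δ
re-weights its tails, with (ε=0, δ=1) the identity. Fitting maximizes the
warped evidence: the closed-form Gaussian log marginal likelihood of
φ(ỹ) plus the log-Jacobian Σ log φ′(ỹᵢ).

**Covariates.** Age enters through a clamped cubic B-spline with three
interior knots at the reference-age quantiles — clamped boundaries make
the basis a partition of unity, and three interior knots are enough
flexibility for smooth lifespan trajectories while remaining identifiable
at a few thousand reference subjects. Sex is a 0/1 indicator. Reference
sites enter as mean-centered one-hot columns, so the intercept represents
the site-averaged population and site effects are additive offsets; the
weight prior regularizes the (deliberate) redundancy between the
partition-of-unity spline block and the intercept. Ages outside the
reference span are clipped to the boundary with a warning rather than
extrapolated, because clamped splines have no honest extrapolation.

**Hyperparameter search.** (log α, log β, ε, log δ) are optimized with
L-BFGS-B from three fixed starting points — identity warp, mildly
right-skewed, mildly left-skewed — with bounds log α, log β ∈ [−10, 10],
ε ∈ [−3, 3], δ ∈ [0.25, 4], and a relative objective tolerance of 1e-9
(≈1e-6 absolute at the objective magnitudes involved). The multi-start
guards against the mild multimodality that warp parameters can induce.
The posterior weight mean and covariance at the optimum are stored.

## Site transfer and z-scores

Recalibration to a new site never refits weights, warp, or precisions.
The warped residuals r = φ(ỹ) − Xw of the target-site controls define an
offset m_s = mean(r) and a scale s_s = sd(r)/sd_pred, where sd_pred is
the model's root-mean predictive SD for those controls. The deviation
z-score of a participant at site s is

    z = (φ(ỹ) − x·w − m_s) / (s_s · sqrt(1/β + x·S·x)),

with S the posterior weight covariance. Controls from a correctly
calibrated site are standard normal by construction, so at the default
threshold the expected null outlier rate per region is Φ(−1.96) = 2.5%.
The default minimum is 10 target-site controls, with a warning below 20.
Whether a transfer step should also adapt the noise precision is an open
design question in this model class; offset + scale is this package's
choice, and it is sufficient to absorb additive site effects and modest
variance mismatches (the calibration tests verify this directly).

Reference sites are calibrated for free: their fitted site-column
contribution becomes the offset, with scale 1.

## Deviation metrics

Outliers are defined by a strict lower-tail comparison, z < threshold
(default −1.96; alternate −1.282, the lower 10% tail, used for
sensitivity reruns); a z exactly at the threshold is not an outlier, and
positive deviations are ignored by default since the question is atrophy
(a two-tailed mode exists but is off). The total outlier count is the sum
over the 169 regions; it equals the Hamming distance between the
participant's outlier vector and the all-zero vector. Pairwise Hamming
distances are computed within groups (d = kᵢ + kⱼ − 2·oᵢ·oⱼ in integer
arithmetic); each participant is summarized by the median of their n−1
distances, medians rather than means because the pairwise distributions
are right-skewed. The median of an even number of distances is the mean
of the two middle values.

## Group inference

Group differences in count-like measures and clinical-score associations
use OLS on [intercept, predictor, age, sex] with the Wald t and two-sided
p for the predictor. Group indicators code the first-listed group as 1
and the second (reference) as 0, so a negative coefficient means the
first group scores lower. Hamming medians and per-region outlier
indicators are compared with the Mann–Whitney U test (U convention,
0 ≤ U ≤ n₁n₂): exact null distribution when there are no ties and
C(n₁+n₂, n₁) ≤ 20,000, otherwise the normal approximation with mid-ranks,
tie correction and continuity correction. Regional tests are corrected
with Benjamini–Hochberg step-up FDR (BH rather than BY; the tests are
positively dependent at worst). Composite cognitive scores are the mean
of per-subtest z-scores relative to control means/SDs, averaging over
whatever subtests a participant completed.

Participants with anomalously high total outlier counts are flagged by a
quartile rule — count > Q3 + 3·IQR within group — as a reproducible
automation of what is usually an eyeballed judgement; the pipeline can
rerun all comparisons without them (`exclude_extremes`). The multiplier
is configurable; 3·IQR flags only far-out points under the right-skewed
count distributions this measure produces.

## Synthetic cohorts

The generator draws, once per region from documented priors: a native
location and scale (thickness ≈ 2.2–2.9 mm with 5–8% dispersion; volumes
around plausible structure means with 8–12% dispersion), cubic age-trend
coefficients on the Gaussianized scale (decline ≈ 0.8 warped-SD per 15
years with mild curvature), and warp parameters (skew ε ~ U(−0.2, 0.2),
δ = 1 by default — the residual distributions of real ROI data are not
characterized in the literature this emulates, so these are deliberately
modest placeholders, not estimates). Sites contribute additive offsets
N(0, 0.3) per region on the warped scale; sex a −0.25 warped-SD offset;
unit noise completes the latent value, and the native measurement is the
inverse warp mapped through the region's location/scale.

The mean structure lives on the *warped* (Gaussianized) scale rather than
being added to a native-scale mean with skewed additive noise. This is a
deliberate design choice: it keeps the generator inside (up to the sample
standardization affine) the model family the fitting code assumes, which
is what makes parameter recovery well-posed — injected site offsets come
back in warped-SD units, injected warp skew is recoverable within ±0.15
at n=2000, and a −k·SD atrophy shift moves z by ≈ −k, giving closed-form
expected outlier counts k·Φ(−1.96+k) + (169−k)·Φ(−1.96) to test against.
Under a flat-trajectory configuration the native residual distribution is
exactly the inverse-warp pushforward of N(0,1), which the Monte-Carlo
skewness oracle in the tests exploits.

Patients get a participant-specific affected-region set: with
heterogeneity h, a Poisson-distributed number of regions (mean = group
burden) is drawn, a fraction (1−h) from a fixed group core list and the
rest at random (h=0 gives identical sets of fixed size). Affected regions
are shifted down by the group effect size in warped-SD units. Clinical
scores are linear-Gaussian in the summed burden, with group-specific
loadings arranged so that global cognition tracks burden in the DLB-like
group while visuo-perception tracks it in the PD-like groups. Default
group sizes (62/34/61) and the burden ordering PD-high < PD-low < DLB
follow the analysed clinical samples this generator stands in for;
burden means (3/8/16 regions at −2.5 SD) were chosen once as a realistic
severity gradient.

**What passing tests show, and what they do not.** The generator draws
regions independently given covariates, uses uniform ages, balanced
sexes, purely additive site effects and exactly sinh-arcsinh residual
shapes. Real ROI data have correlated regions, demographically skewed
sites, site-by-age interactions, scanner artefacts and QC failures. Tests
passing here establish that the *pipeline arithmetic* is correct and that
the method recovers truth when its assumptions hold — not that the model
is adequate for any particular real dataset.

## Problem sizes and determinism

The acceptance-level checks run at the scale the method is meant for: a
reference of 2000 controls over 4 sites (all 169 regions, fitted in well
under a minute), 100 controls per held-out site for recalibration, 1000
held-out null participants for the calibration check, and clinical groups
of 34–150 for the directionality and recovery checks. Unit tests use a
6-region subset and smaller cohorts. Every random draw derives from a
single integer seed via numpy `SeedSequence` spawning; rerunning the
pipeline with the same config and seed reproduces every output file
byte for byte.

With 100 recalibration controls the null outlier rate is expected to sit
slightly above 2.5% (≈2.6–2.85%): the offset and scale corrections are
noisy with SE ≈ 0.1 and the tail probability is convex in both, so
estimation noise inflates the rate. This is a property of the transfer
design at that control count, not a bug; with thousands of calibration
controls the rate returns to 2.5% (verified in development runs and by
the large-pool unit test).

## Known limitations

- One model per region: no spatial pooling, no multivariate calibration.
- The warp has two parameters applied after a fixed standardization;
  location/scale-augmented warps (four-parameter sinh-arcsinh) are out of
  scope, which slightly limits fidelity for strongly skewed regions.
- Site effects are additive offsets (plus transfer-time scale); no
  site-by-age interactions.
- Hierarchical/GP normative models, vertex-wise analysis, longitudinal
  visits and image processing are out of scope.
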