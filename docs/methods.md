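# Methods note

Statistical model, generator scope, numerical choices, and limitations
of the `painmediate` package. Everything empirical stated here was
computed with this package; commands or seeds are given where relevant.

## 1. Model

### 1.1 Two-level GLM (behavior)

Level 1 fits OLS within each subject; level 2 tests the subject
coefficients with a one-sample t-test ("summary statistics" approach).
This is exact for balanced within-subject designs and yields the
conventional report (β, 95 % CI, t(n−1), p, Cohen's d with
d·√n = t). Cues are coded −1/+1 and temperature −1/0/+1, so the
high-minus-low difference is twice the coefficient. Cue effects on
pain and SCR are estimated on the medium-temperature (49 °C) trials
only, where stimulus intensity is constant by construction. Cue-by-time
interactions use the trial counter within each cue condition (centered
per subject) by default.

### 1.2 Three-path multilevel mediation

Per subject, three OLS regressions with a shared covariate set estimate
a (X→M), b and c′ (Y ~ M + X), and c (Y ~ X). Because all three use
the same design columns, c = c′ + a·b holds as an algebraic identity of
OLS projections — the package asserts it to 10⁻¹⁰ relative error over
1000 random datasets. The group mediated effect is the mean of the
subject products aᵢbᵢ, which decomposes as
mean(a)·mean(b) + (n−1)/n·cov(a,b); both components are reported.

Group inference options:

- `method='bootstrap'` (behavioral default): bias-corrected percentile
  bootstrap over subjects, one common resampling plan across all five
  paths; two-sided p inverts the BC interval
  (p = 2·min{Φ(w), 1−Φ(w)}, w = Φ⁻¹(G(0)) − 2·z₀); p-values are floored
  at the bootstrap resolution 2/(B+1).
- `method='t'`: one-sample t-test on the subject estimates (identical
  point estimates and decomposition).

### 1.3 Voxelwise mediation and map inference

Each voxel's single-trial response is the mediator; per-subject paths
are computed for all voxels at once via Frisch–Waugh–Lovell
residualization (identical to full OLS), and c′ follows from the exact
identity. FDR control is Benjamini–Hochberg step-up (statsmodels)
pooled across the tested paths (a, b, ab) of a model; the attained
voxel-level p cutoff is reported. Display tiers (p < .01, p < .05
uncorrected) are pruned to connected components (scipy.ndimage,
26-connectivity default) containing at least one FDR voxel.
Conjunctions use the conjunction null (each constituent individually
significant); overlap uses the Dice coefficient, defined as 0 with a
warning when both sets are empty. Signature scoring is the dot product
of a weight map with each trial image.

### 1.4 Network decoding

Wedge similarity is the Pearson r between a (thresholded, signed) map
and each network's binary indicator, with wedge radius max(r, 0).
Subnetwork contrasts z-score each subject's unthresholded effect map
across in-mask voxels (offset/scale invariant), average within
subnetwork, and run a paired t-test on the Social − CS difference.
The octant statistic classifies each voxel's (Social ab, CS ab) pair
into eight 45° sectors numbered clockwise from the +y axis (octant 1 =
uniquely positive CS, 2 = shared positive, 3 = uniquely positive
Social, 8/4 = sign-discordant); boundaries at odd multiples of 22.5°
are half-open in standard (counterclockwise) angle coordinates, and
(0, 0) maps to "none". Per octant we accumulate voxel counts and
SSD = Σ(x² + y²), flagging the SSD peak. Term decoding returns the
top-k positive Pearson correlations over a named map stack with
case-insensitive deduplication.

### 1.5 Single-trial estimation

Outlier time points: recursive step-down detection (≤ 3 iterations by
default). A time point is flagged when the cross-channel mean deviates
from the kept-sample median by > 10 m.a.d., or when its Mahalanobis
distance over slice-wise means and spatial SDs (covariance shrunk
toward its diagonal when ill-conditioned) deviates by > 10 m.a.d.
Flagged points leave the reference statistics and the test repeats, so
large artifacts cannot mask smaller ones; the masking route is the
non-robust covariance (the m.a.d. itself tolerates heavy
contamination). The m.a.d. is scaled by 1.4826 (consistent for a normal
SD); pass `mad_scale=1.0` for the raw convention.

Single-trial GLMs return per-trial VIFs (1/(1−R²) against all other
columns); trials with VIF > 2.5 (strict) are excluded and logged.
Exactly collinear trial regressors are tolerated (VIF = ∞, removed by
the filter); other rank deficiencies raise with the offending column
names. SCR amplitudes come from OLS deconvolution with a gamma-family
canonical kernel (shape 3, scale 1.3 s, unit peak, mode at 2.6 s) after
zero-phase 4th-order Butterworth low-pass filtering at 1 Hz.

### 1.6 Classification

Leave-one-subject-out forced choice: a linear SVM (scikit-learn SVC)
trained on all other subjects' labeled Social/CS images (feature
standardization from training-fold statistics only) scores the held-out
pair; the subject is correct iff the Social image gets the higher
decision value. Significance is an exact two-sided binomial test
against 0.5.

## 2. Synthetic generator

### 2.1 Design

Cell counts (CS × temperature × social) are allocated deterministically
by largest-remainder from the contingency table, so the marginals —
24/48/24 trials at 48/49/50 °C, CS-low → {48, 49} and CS-high →
{49, 50} at 24 each, social 50/50 within every cell — are exact for
every seed; the seed randomizes only trial order. Per-subject orders
come from children of a master `SeedSequence`, so earlier subjects are
unchanged when the cohort grows. Social stimuli are 10 values per trial
from N(0.3, 0.15) or N(0.7, 0.15) restricted to [0, 1] by rejection
resampling (the realized marginal is the truncated normal, checked
against the closed form).

### 2.2 Behavior

Expectation = subject intercept + aₛᵢ·g(t)·S + a_cᵢ·h(t)·C + noise,
with g(t) a linear decay of the social weight to 60 % over the 48
within-condition trials and h(t) = 1 − exp(−(t−1)/12) a saturating
CS learning curve (both replaceable or disableable). Pain = subject
intercept + temperature slope·T + γᵢ·expectation + direct cue effects
+ noise; SCR = intercept + social effect + noise. All coefficients have
configurable between-subject SDs, plus an explicit cov(aₛ, γ) for
planted moderated mediation. Ratings are clipped to [0, 100]; the clip
fraction is recorded and warned about above 5 % (defaults sit near
0.5 %). `behavior_ground_truth` returns the implied group paths,
averaging g and h over the 49 °C trials the mediation actually uses.

### 2.3 Brain

On a 20³ grid (default; 3 mm affine), three disjoint voxel populations
of 200 are planted: social mediators and CS mediators track a latent
L = aᵢ·cue + η and add bᵢ·L to pain; pain-only voxels track a
cue-independent latent that feeds pain; remaining voxels are pure
noise. (aᵢ, bᵢ) are drawn with configurable means, SDs and covariance,
so E[aᵢbᵢ] = mean(a)·mean(b) + cov(a, b) is known exactly. The returned
trial table has pain regenerated to include the mediator terms; the
per-subject (aᵢ, bᵢ) and voxel labels are returned for scoring.

### 2.4 Scope

The generator emulates the *statistical* structure of the experiment —
design, contingencies, mediation paths, time-varying cue weights,
planted voxel populations — not the physics: no hemodynamics, spatial
smoothness, autocorrelated noise, drift, or motion. Grid size, planted
effect sizes, and noise SDs are package choices tuned to give the
analysis chain realistic (not saturated) operating points at n = 36.

## 3. Numerical choices and measured calibration

- **Voxelwise group inference defaults to the t-test, not the BC
  bootstrap.** Measured with this package: the bias-corrected
  percentile bootstrap p-value for the group ab runs anti-conservative
  at a few dozen subjects — type-I error 0.075–0.082 at α = 0.05 over
  1000 null simulations — and propagating those tail p-values through
  BH yields a realized false-discovery proportion ≈ 0.14 on the 20³
  grid. The one-sample t on subject estimates measures 0.046–0.058
  type-I (three seeds, 500 sims each) and FDP 0.030–0.041 with planted
  sensitivity ≥ 0.99. Point estimates are identical between methods.
  The bootstrap remains available (`method='bootstrap'`) and is the
  behavioral-mediation default, where the estimate, SE, CI and
  decomposition — not extreme tails over thousands of tests — are the
  quantities of interest.
- **FDP accounting.** The acceptance FDP is counted at the
  (path, voxel) pair level — the unit BH thresholds when pooling
  paths — with generative truth per pair (for the social model:
  pure-noise voxels null on all paths; CS-mediator and pain-only voxels
  null on a and ab, truly active on b). Counting instead the fraction
  of *union*-discovered voxels that are pure noise gives ≈ 0.057; that
  functional triple-counts null voxels' chances while collapsing their
  discoveries, and is not the expectation BH controls.
- **Bootstrap determinism and resolution.** One common subject-
  resampling plan (a counts-matrix product) is shared across paths and
  voxels; p-values are floored at 2/(B+1).
- **Exact identities over tolerances.** c = c′ + a·b is computed from
  the same projections, not re-estimated, so tests assert it near
  machine precision; zero-noise generator profiles recover planted
  parameters to 10⁻⁹ (with the time-varying CS term disabled in the
  exactness profile, since its finite-sample cross-term Σh(t)·C·S ≠ 0
  otherwise enters the OLS social coefficient).
- **m.a.d. scaling.** 1.4826 by default so the threshold has an
  interpretation in normal-SD units; configurable because raw-m.a.d.
  conventions exist and change sensitivity by that factor.

## 4. Limitations

- The t-default for voxelwise inference assumes approximately normal
  subject-level path estimates; with 96 trials per subject the CLT
  serves well, but heavy-tailed first-level noise would degrade both
  methods.
- The BC bootstrap miscalibration was measured for this estimator at
  n ≤ 36 with 10⁴ resamples; larger cohorts narrow the gap.
- FDR control is guaranteed under independence/PRDS; planted-population
  voxels share a latent and are therefore positively dependent, which
  BH tolerates, but adversarial dependence structures are untested.
- The forced-choice permutation null is exchange of the two images
  within subject; it does not probe feature-level leakage beyond what
  training-fold-only standardization prevents.
- Moderated mediation at second level flags influential subjects
  (leverage, ±3 SD) but does not refit robustly; with n ≈ 36 a single
  extreme subject can still dominate, which is why flags are surfaced.
- Synthetic SCR is a per-trial amplitude model; the deconvolution
  module assumes onsets are known and responses are linear-time-
  invariant.
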