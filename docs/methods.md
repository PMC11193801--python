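# Methods

`wmlearn` reimplements, as a tested pipeline on synthetic data, an analysis
that asks whether the *existing* microstructure of major association white
matter tracts predicts individual differences in two learning outcomes that
arise from a single sensorimotor training session: learning to draw a set of
unfamiliar symbols (drawing learning) and learning to visually recognize
them (recognition learning).  This note documents the model and procedure,
the tunable parameters, what the synthetic generators do and do not emulate,
the numerical choices, and the known limitations.

## The analysis

**Features.** One scalar per tract per participant: mean fractional
anisotropy (FA) along the tract.  The default tract set is the 11
association tracts per hemisphere (SLF1and2, SLF3, ILF, IFOF, Arc, pArc,
TPC, MDLFang, MDLFspl, VOF, FAT), 22 predictors in total; the list is a
configuration input.

**Tract profiles (`tractometry`).** For each bundle of streamlines (TCK,
RAS mm) and an FA volume (NIfTI-1):

1. streamlines outside the closed length interval [10, 200] mm are dropped
   ("shorter/longer than" is read as strict, so the boundary is kept);
2. streamlines are oriented consistently against a medoid-like reference
   (the streamline whose mean point is nearest the bundle mean); the global
   direction is canonicalized so orientation is idempotent and invariant to
   reversing the whole bundle;
3. each streamline is resampled to 200 nodes equally spaced in arc length
   (linear interpolation along the polyline, endpoints preserved);
4. aberrant streamlines are removed: a streamline is discarded when its
   mean node-wise distance to the bundle core exceeds mean + 4 SD of those
   distances, or its length deviates from the mean length by more than
   4 SD.  Statistics and core are recomputed after each pass, up to 5
   passes (recomputation is the standard outlier-rejection practice; the
   cap bounds runtime).  The distance summary is the mean over nodes; a
   `max` variant is available via an argument;
5. FA is sampled trilinearly at every node of every streamline and averaged
   per node with Gaussian weights in the distance to the core,
   w_sk ∝ exp(−d_sk² / 2σ_k²), σ_k the SD of the node-k distances — the
   along-tract-profile convention of AFQ-style tractometry.  The upstream
   literature states only "weighted by the distance from the core", so an
   inverse-distance kernel is provided as a sensitivity switch
   (`kernel="inverse_distance"`);
6. the tract feature is the unweighted mean over the central 160 nodes
   (20 trimmed per end, against partial-volume effects near cortex).

**Learning outcomes (`behavior`).** Drawing learning is the per-participant
OLS slope of draw duration (seconds) over the repetition index 1..10,
pooled over the 40 symbols, after removing trials strictly outside the
participant's mean ± 3 SD (single pass, no recomputation).  The repetition
index is the default regressor; `index="chronological"` (1..400) is the
alternative reading.  A bounded double-exponential learning-curve fit
(y = c + A₁e^{−k₁r} + A₂e^{−k₂r}, rates in [1e-4, 10], 5 seeded
multi-starts) is provided for model comparison; on near-linear data its
optimum lies on a flat parameter valley, so any finite-cost termination is
reported with its SSE rather than demanding formal convergence.
Recognition learning is the proportion of correct responses over responded
2-AFC trials (40 targets + 40 distractors; timeouts excluded from numerator
and denominator).  A cohort-level regression of accuracy on mean RT checks
for a speed-accuracy trade-off.  Participants are excluded for SNR < 15,
framewise displacement > 2 mm, a visible artifact, or recognition accuracy
≤ 0.5 (chance level; the boundary is excluded).

**Tract selection (`model_selection`).** The relaxed lasso: features are
z-scored (divided by the sample SD; a `variance` mode implements the
literal "divided by their own variance" reading, but SD-division is what
makes the standardized coefficients comparable), the outcome is centered,
and the lasso

  min_β 1/(2n) ‖y − Xβ‖² + λ‖β‖₁

is solved by cyclic coordinate descent with soft-thresholding, warm starts
along the descending grid λ_max·10^linspace(0, −4, 100) with
λ_max = max_j |x_jᵀy|/n, and convergence when the largest coefficient
change in a sweep is below 1e-8.  The penalty is chosen by leave-one-out
cross-validation with the minimum mean squared prediction error;
standardization parameters are recomputed inside each training fold to
avoid leakage, and exact ties break toward the larger (sparser) λ.  The
final model is a plain OLS refit on the selected support (full debiasing —
no intermediate relaxation), reporting β, SE = √diag(σ̂²(XᵀX)⁻¹) with
σ̂² = SSR/(n−|S|−1), and R². An empty support yields the intercept-only
model with R² = 0.  Complementary marginal regressions fit one
single-tract OLS per (tract, outcome) with uncorrected two-sided t-tests at
α = 0.05.

The coordinate-descent inner loop uses covariance updates (precomputed
Gram matrix XᵀX/n, so a coordinate step costs O(p) rather than O(n) — the
right trade in this n > p regime) and is JIT-compiled with numba so that
LOOCV-based Monte Carlo validation runs at study scale; a pure-Python
implementation of the identical sweep is kept for cross-checks and for the
objective-monotonicity property test.  The solver is validated against
scikit-learn's `Lasso` and, for LOOCV-min selection, reproduces
R `glmnet::cv.glmnet(nfolds=n)` supports exactly on shared fixtures.

**Transfer tests (`transfer`).** Whether the tracts selected for one
outcome explain variance in the other outcome beyond that outcome's own
model is tested two ways.  `cox_test(y, X, Z)` is the Pesaran linear-model
Cox statistic for the null "the original model Z is correct and X adds
nothing": fit y ~ Z and y ~ X, regress the Z-model's fitted values on X,
form σ̂²_XZ = σ̂²_Z + ‖M_X ŷ_Z‖²/n, c = (n/2)·ln(σ̂²_X/σ̂²_XZ), and
v = σ̂²_Z·(ŷ_Zᵀ M_X M_Z M_X ŷ_Z)/σ̂⁴_XZ; z = c/√v is asymptotically
standard normal, negative when X explains leftover variance.
`j_test(y, X, Z)` augments the Z model with the X model's fitted values and
t-tests that coefficient (df = n − cols(Z) − 2).  Both are numerically
identical to `statsmodels` `compare_cox`/`compare_j` and to R
`lmtest::coxtest`/`jtest` on shared data.  Projections use orthonormal
design bases (QR), never explicit inverses.  The z statistic is asymptotic;
results at n < 100 carry a `small_sample` flag.  The transfer model's R²
is the plain OLS R² of one outcome on the standardized tracts selected for
the other.

A caution established during validation: when the competing design X is
*strictly orthogonal* to Z, the Cox variance term collapses and the test
over-rejects badly in finite samples (~25% at n = 200; R's `lmtest`
behaves identically).  With competing predictors drawn from the same
correlated feature pool — the realistic situation for tract FA columns —
both tests are well calibrated; the calibration checks therefore use that
structure.

## Synthetic data

The generators emulate the study design end to end with planted,
recoverable ground truth; they write the same TCK/NIfTI/TSV formats the
readers consume, so the pipeline cannot distinguish synthetic from real
inputs.

* **Bundles** are tubes around a cubic-spline centerline (arc-length
  sampled).  Each streamline carries a constant radial offset drawn
  uniformly in a disk whose radius is twice the configured jitter SD (so
  each Cartesian component has that SD), plus small per-node Gaussian noise
  (5% of the jitter SD by default).  The bounded cross-section is both
  anatomically sensible (fascicles have finite extent) and makes the 4-SD
  cleaning rule separate planted outliers from inliers without false
  positives; a Gaussian offset distribution would place occasional inliers
  beyond any SD-based threshold.  Planted outliers are displaced 10 mm
  (configurable) perpendicular to the centerline and recorded.
* **FA volumes** are background plus per-tract tubes (voxels within the
  tube radius of the centerline take the tract's value) or an affine
  gradient field a + g·x for interpolation checks.  In the end-to-end
  pipeline each participant's volume contains one straight tube per tract
  on an 18 mm lattice (6 mm radius, 2 mm voxels) whose value is that
  participant's drawn FA, so the tractometry stage can be checked for exact
  feature recovery.
* **Cohort features** are multivariate normal: per-tract means spread over
  0.38–0.55, SD 0.035, equicorrelation ρ = 0.3 (a single interpretable
  collinearity knob, chosen as a realistic inter-tract FA correlation).
* **Drawing learning**: latent slope = −0.030 + 0.010·(Σ_k β_k z_k + ε)
  s/repetition, with β the standardized true coefficients (defaults mirror
  the two-left-tract structure: L_pArc 0.2118, L_SLF3 0.1772) and ε scaled
  analytically so the population R² on the true support equals the target
  (default 0.118): ε_sd = √(Var(βᵀz)·(1−R²)/R²), Var(βᵀz) =
  (1−ρ)Σβ² + ρ(Σβ)².  The 0.010 s/rep scale maps the standardized outcome
  into realistic slope units.
* **Recognition learning**: latent accuracy is logistic,
  p_i = σ(1.0 + s·Σ_k α_k z_k + ν).  The configured coefficients (defaults
  L_MDLFspl −0.629, L_TPC −0.4025) act as relative weights: s and the
  latent noise ν are solved so the true tracts explain a target fraction
  (default 0.1) of a total latent logit SD of 0.375.  These defaults give a
  cohort accuracy mean ≈ 0.73, SD ≈ 0.09, about 0–2 chance-level
  participants per 60, and a true-support accuracy R² ≈ 0.07 — the
  emulated study's regime.  With the target set to `None` the coefficients
  are used verbatim with no latent noise.
* **Trials**: drawing durations a_i + b_i·r + u_s + ε (symbol effects
  u_s ~ N(0, 0.1 s), trial noise 0.25 s), clipped to (0.2, 4.0] s; with
  probability 0.01 a trial's duration is tripled before clipping and its
  index recorded.  Recognition trials are Bernoulli(p_i) per responded
  trial with log-normal RT (median 0.55 s, capped at the 1 s timeout) and a
  5% timeout probability.  QC tables plant SNR/motion/artifact violations
  exactly where configured.

**What the generators do not emulate** — and hence what green tests do not
establish about real data: diffusion signal formation, scanner noise,
crossing-fiber geometry, tract segmentation errors, partial-volume FA bias
(tubes are homogeneous, so profile trimming is exercised but not stressed),
non-Gaussian behavioral noise, learning curves that are genuinely
exponential, and any true nonlinearity in the FA–outcome mapping.

## Numerical choices

* Trilinear sampling happens in continuous 0-based voxel space after the
  inverse affine; out-of-grid samples return a configured background value
  with a flag rather than raising (the profile stage, which knows the
  context, raises if any node is out of bounds).
* Sample SDs use ddof=1 throughout (standardization, cleaning thresholds,
  trial outlier rule).
* Coefficients below 1e-14 after soft-thresholding are snapped to zero so
  the all-zero solution at λ_max is exact despite last-ulp rounding.
* The pipeline derives all stage seeds from one global seed via
  `SeedSequence`; reports are serialized with sorted keys and repr floats,
  so identical (config, seed) runs are byte-identical.
* Nestedness of competing designs is detected by column-space ranks; the
  J-test refuses designs whose augmented matrix conditions worse than 1e8.

## Known limitations

* LOOCV-min lasso over-selects at small n (supports of 8–15 at n = 48 are
  common under strong signal with ρ = 0.3) — verified to be the method,
  not the implementation, by exact agreement with glmnet.  Consequences
  for the transfer analysis are discussed with the validation results.
* The Cox z is asymptotic and miscalibrated when competing designs are
  orthogonal (see above); interpret transfer tests between uncorrelated
  predictor sets with care.
* Profile weighting reflects one reading of "weighted by distance from the
  core"; both kernels are exposed because the upstream convention is not
  fully specified.
* The double-exponential fit reports a best-effort bounded optimum; on
  effectively linear data its parameters are not identified (only the
  fitted curve is meaningful).
* Acceptance-scale Monte Carlo sizes (20–200 seeds, 500–2000 test
  simulations) were chosen as the package's own balance of statistical
  resolution against desk-scale runtime.
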