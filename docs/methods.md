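# Methods

## Problem and approach

Benign and malignant myxoid-containing soft-tissue tumors overlap widely
in mean apparent diffusion coefficient (ADC), because the water-rich
myxoid matrix raises ADC in both. What differs is *spatial arrangement*:
benign lesions in this family (mostly neurogenic tumors) carry a fibrous
low-diffusivity center inside a myxoid high-diffusivity periphery, while
the malignant lesions are dominated by near-uniform myxoid matrix. The
package quantifies that arrangement with texture statistics of the ADC
map inside a tumor ROI and asks which statistic best separates the two
groups.

Because no patient images are distributed with this package, every stage
is exercised on synthetic tumor phantoms whose construction encodes
exactly that histologic contrast. The phantom cohort is therefore a
*model of the study design*, not of any particular patient.

## ADC estimation

The mono-exponential signal model is

    S(b) = S0 · exp(−b · ADC),   b ∈ {0, 400, 800} s/mm²

and the voxelwise estimate is minus the slope of the ordinary
least-squares line of ln S(b) on b. Choices:

* **Unweighted log-domain fit over all three b-values.** A two-point
  formula and a weighted fit are standard alternatives; the joint
  unweighted fit is the simplest defensible reading of "exponential
  fitting over three b-values" and is what the grid-search oracle in the
  tests verifies against.
* **Non-positive signals** at some b are dropped voxelwise (ln is
  undefined); a voxel with fewer than two usable points becomes NaN and
  is excluded downstream rather than raising, so one dead voxel cannot
  kill a cohort run.
* **Negative slopes clamp to ADC = 0**: at low SNR the b=800 signal can
  exceed the b=0 signal by chance; a negative diffusivity is unphysical
  and downstream statistics must not crash.

## Texture features

* **Global** (raw ADC values in the ROI, no quantization): mean, sample
  SD (n−1), skewness m₃/m₂^1.5 and **non-excess** kurtosis m₄/m₂²
  (Gaussian → 3), with mᵣ the population central moments. The non-excess
  convention is used because a Gaussian-like lesion should sit at 3.
  Constant ROIs return NaN for skewness/kurtosis rather than raising.
* **Quantization**: equal-width binning of the per-ROI [min, max] range
  into L = 64 levels, level = 1 + ⌊L(x−min)/(max−min)⌋ with the maximum
  clamped to L. Equal-width on the per-lesion range is the dominant
  radiomics convention for a fixed level count; it makes every feature
  scale-free in ADC but sensitive to the lesion's own dynamic range
  (see "interactions" below).
* **GLSZM** (regional): zones are maximal 26-connected components of
  equal level inside the ROI (6-connectivity selectable). With M(m,n)
  zones of level m and size n and N_Z total zones,
  intensity variability = Σₘ(Σₙ M)²/N_Z and size-zone variability =
  Σₙ(Σₘ M)²/N_Z.
* **GLCM** (local): for each of the 13 unique 3D offsets at 1-voxel
  distance (the 26-neighbourhood modulo sign), ordered level pairs with
  both voxels in the ROI are counted, symmetrized by adding the
  transpose, normalized to sum 1, and the 13 matrices averaged with
  equal weight (directions with no valid pair are skipped and the
  average renormalized). Offsets are measured in index space: the slice
  thickness (5 mm) is much larger than the in-plane pixel (1.37 mm), and
  "1-voxel distance" is a statement about the grid, not physical
  distance. The seven features use the standard formulas (energy Σp²,
  entropy −Σp ln p with natural log, correlation (Σij·p − μ²)/σ²,
  contrast Σ(i−j)²p, homogeneity Σp/(1+|i−j|), variance Σ(i−μ)²p,
  maximum probability max p). Natural-log entropy is a convention
  choice; log2 differs only by a constant factor.

Reported clinical values of GLCM correlation in this problem domain
(~0.007–0.014) are far below what the standard formula produces on any
realistic map, indicating a non-standard normalization in the original
in-house analysis; this package implements the standard formula and does
not attempt to reverse-engineer the variant.

## Phantom cohort

Each subject is an ellipsoidal tumor (axis ratios 1 : 0.8 : 0.7, chosen
fixed for determinism and configurable) centred in its own grid at
1.37 × 1.37 × 5 mm voxels (a 350 mm FOV / 256 matrix, 5 mm sections).

* **benign-like**: ADC = 1.2×10⁻³ mm²/s inside `core_fraction = 0.7` of
  the ellipsoid radius (fibrous center), 2.6×10⁻³ outside (myxoid rim),
  plus *white* spatial jitter of SD 0.3×10⁻³. The resulting mean ADC
  (~2.1×10⁻³) and the bimodal, grainy map encode the heterogeneous
  histology.
* **malignant-like**: uniform ADC = 1.914×10⁻³ plus *smooth* jitter
  (Gaussian correlation length 8 mm, SD 0.3×10⁻³): a spatially
  homogeneous map at the group mean ADC scale of the malignant lesions.
* **Signal**: per b-value, Rician magnitude
  √((A+n₁)² + n₂²), A = S0·e^(−b·ADC), n ~ N(0, S0/SNR), SNR = 100,
  drawn independently per b-value volume (separate acquisitions).
  Rician (not Gaussian) noise is the physically correct magnitude-MRI
  law and reduces to Gaussian at high SNR; at SNR → ∞ the noise-free
  magnitude is returned exactly.
* **Covariates**: ages normal truncated at 18 (benign 53.0 ± 12.7,
  malignant 60.8 ± 13.4 years), sex Bernoulli (female fraction 12/23 vs
  6/17), tumor volume log-normal moment-matched to 15.6 ± 14.8 vs
  139.4 ± 179.2 cm³ — SDs of this size relative to the means rule out a
  normal law on positive support.

**Why the jitter structure matters.** Quantization uses the per-ROI
min–max range, so a homogeneous lesion's noise is stretched across all
64 levels. If both classes carried independent voxelwise jitter, the
*uniform* lesion would show the larger level-to-level differences —
i.e. higher GLCM contrast — inverting the biological expectation. Tissue
ADC variation is spatially correlated; giving the malignant-like
phantom long-range smooth jitter (neighbouring voxels nearly equal) and
the benign-like phantom short-range grainy jitter plus the core/rim
boundary reproduces the expected ordering of every local feature. The
correlation length is a first-class phantom parameter
(`jitter_correlation_mm`, 0 = white).

**What the phantom does not model**: scanner artifacts (ghosting,
distortion, partial volume), perfusion/IVIM bi-exponential decay,
irregular tumor shapes, infiltrative margins, and inter-subject
variation of the compartment ADC values (class templates are fixed;
only geometry, covariates and noise vary per subject). Consequently
group separation on the phantom cohort is far cleaner than clinically
realistic — contrast's AUC is typically 1.0 rather than ~0.9 — and
passing the cohort-level checks demonstrates that the *machinery*
recovers a built-in spatial-heterogeneity contrast, not that these
features achieve any particular clinical accuracy.

## Statistics

* **Normality**: one-sample KS against a normal with estimated moments,
  Lilliefors-corrected (plain KS with estimated parameters is
  anti-conservative).
* **Group means**: pooled-variance Student t-test (Welch would be the
  robust alternative; pooled matches the classical design), two-sided.
* **Sex**: Pearson chi-square on the 2×2 table, df = 1, no continuity
  correction (this convention reproduces p = 0.289 on the 23 = 12F:11M
  vs 17 = 6F:11M split).
* **ANCOVA**: OLS of feature on intercept + group + age + sex + volume;
  the "adjusted p" is the two-sided partial t-test of the group
  coefficient. Rank-deficient designs (e.g. single-sex cohorts) raise an
  error naming the collinear column. Note that with irrelevant
  covariates the adjusted p differs from the unadjusted p by O(k/√n)
  in the t-statistic; the two converge only for large cohorts.
* **ROC**: AUC is the normalized Mann–Whitney statistic with half credit
  for ties; the direction is auto-chosen so AUC ≥ 0.5 and reported as
  ">" (positive calls above the cutoff) or "≤". The operating threshold
  maximizes Youden's J = sensitivity + specificity − 1 over observed
  values, ties broken toward higher specificity (a deterministic rule is
  needed; specificity is the customary priority for a rule-in test).
  Sensitivity/specificity carry exact binomial (Clopper–Pearson) 95%
  CIs; the AUC carries a DeLong-variance normal CI and a z-test against
  0.5. DeLong is used for the AUC (an exact binomial CI is ill-defined
  for a correlated pair statistic; the binomial-exact option in common
  clinical software most naturally attaches to sensitivity/specificity,
  and both interval families are produced).
* **Pairwise AUC comparison**: correlated-ROC DeLong covariance on the
  shared subjects; the table layer orients each feature before
  comparing (so differences refer to the reported ≥0.5 areas), while the
  core test uses scores as given — internal re-orientation would fold
  the null distribution and destroy p-value uniformity. Bonferroni
  multiplies by the number of pairs actually compared, capped at 1.
  Both raw and adjusted p are always reported.
* **AUC labels**: excellent [0.9, 1], good [0.8, 0.9), fair [0.7, 0.8),
  poor [0.6, 0.7), failure [0.5, 0.6).

The DeLong machinery (fast midrank algorithm) was cross-checked against
R's `pROC` (AUC, variance and paired p agree to ≥6 decimals) and is
tested against a stratified-bootstrap variance oracle.

## Problem sizes and numerical choices

Cohort runs use the per-subject grids implied by the drawn volumes
(typically 10³–10⁵ ROI voxels; a full 40-subject cohort takes ~3 s).
Stability checks use 20 independently seeded cohorts. Oracle-equivalence
tests use 200 random ROIs of ≤ 6×6×4 voxels and ≤ 8 levels, where
explicit-loop references are exact. Type-I calibration uses 2000
replicates per test at n = 40 (23/17). Probability matrices are checked
to Σp = 1 within 1e−9 and symmetry within 1e−12; feature/oracle
agreement is asserted at 1e−10.

## Known limitations

* Phantom class templates are fixed population values; the generator
  produces idealized separation (see above).
* GLCM correlation follows the standard formula and will not match
  in-house variants with other normalizations.
* The ADC fit is mono-exponential; perfusion contamination at b = 0
  (IVIM) is out of scope and would bias ADC upward on real data.
* Volume-to-shape conversion uses fixed axis ratios; real lesions'
  shape variation (and its effect on GLSZM size spectra) is not
  emulated.
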