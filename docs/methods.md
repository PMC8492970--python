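# Methods

This note documents the models, parameter choices and numerical conventions
behind `hemifc`, and what the phantom-based tests do and do not establish.

## Homotopic connectivity model

VMHC treats the brain as midline-symmetric at the voxel level: voxel
(i, j, k) is paired with (N_x − 1 − i, j, k) on the first (left–right) axis
of the canonical grid. The statistic is the Pearson correlation r of the
pair's preprocessed time series, reported as Fisher z = atanh(r) so maps can
be averaged and compared across subjects. The pair's value is written to
both voxels, so every map is exactly mirror-symmetric; downstream cluster
records exploit this by merging exactly mirrored components into single
bilateral (±x) rows.

Correlations are clipped to |r| ≤ 1 − 1e−7 before atanh so degenerate
(perfectly correlated) inputs stay finite; zero-variance series get r = 0
plus a QA flag rather than NaN.

Real data require nonlinear registration to a symmetric template before any
of this is meaningful. The package does not implement registration: phantom
grids are midline-aligned by construction, and this substitution is recorded
in the provenance of every run. With an odd left–right extent the
midsagittal plane would pair with itself (r ≡ 1, uninformative); those
voxels are excluded from the mirror map, and the default grid uses an even
extent so the case never arises.

## Phantom generative model

The phantom exists so that every stage can be verified against known ground
truth at desk scale. Defaults: 24×28×24 grid of 3 mm voxels, 164 time
points at TR 2.2 s, 24 diffusion directions at b = 1000 s/mm² plus one b=0.

**Tissue.** Concentric ellipsoids: CSF core, WM shell, GM rind, mirror-
symmetric by construction. Per-subject probability maps are 0.92 inside the
compartment and 0.04 elsewhere in the brain, plus symmetric noise
(SD 0.02) and a mild asymmetric perturbation (SD 0.02) that exercises the
flip-average symmetrization. The group-mask thresholds (0.2 GM, 0.8 WM)
then recover the compartments.

**BOLD.** For each mirrored voxel pair in a parcel with planted correlation
ρ and noise scale σ (default 0.2):

    x(t) = s(t) + σ·e1(t)
    y(t) = ρ·s(t) + sqrt(1 − ρ²)·e2(t) + σ·e3(t)

with s, e1, e2, e3 independent unit-variance Gaussian series, giving the
closed-form population correlation ρ_eff = ρ / (1 + σ²). This attenuated
value — not the nominal ρ — is the recovery target everywhere. Default
parcels plant ρ ordered NC > VMCI > MCI (0.8/0.6/0.4 in the main parcel);
these magnitudes are this package's own choice of a strong, clearly ordered
effect, not measured values. Brain voxels outside parcels carry independent
noise; CSF voxels share a common fluctuation (so the CSF regressor is
meaningful); all brain voxels get a 1000-unit baseline and a random linear
drift (exercising the detrend); optional spike frames add a global
artifact matched by a >1 mm step in the motion trace.

**Motion.** A clipped Gaussian random walk (translation steps SD 0.08 mm
clipped at ±0.15, rotation steps SD 8e−4 rad clipped at ±1.5e−3) whose
Power framewise displacement averages ≈ 0.3 mm — the magnitude typical of
elderly cohorts — with a guaranteed spike-free maximum of 0.675 mm < 1 mm.
Spikes are persistent x-translation steps (default 2 mm).

**DWI.** Single-tensor signals S = S0·exp(−b·gᵀDg), noiseless given the
tensor field. Baseline tensors: WM prolate (1.7, 0.3, 0.3)×10⁻³ mm²/s with
principal axis along y (mirror-invariant), GM isotropic 0.8×10⁻³, CSF
3.0×10⁻³. Group effects are planted as per-parcel eigenvalue multipliers
(default: MCI gets λ₁×1.5 in one WM parcel — raising AD, MD and FA — and an
isotropic ×1.25 in another — raising AD and MD, leaving FA unchanged).
Because the signal model is noiseless, between-subject variability comes
from a global per-subject log-normal eigenvalue jitter (SD 0.04); without
it, within-group variance would be zero and group t-tests undefined.

**Covariates.** Age, sex, education and MMSE are drawn per group from
normal/Bernoulli distributions with means and SDs typical of NC/VMCI/MCI
cohorts (MMSE means 28.86/25.99/22.08, clipped to [0, 30]). They are
synthetic draws; no claim is made of matching real marginals, and by
default they carry no planted group effect other than MMSE's mean shift.

**Determinism.** Every random stream is keyed by (seed, CRC32(subject id),
stream index) through numpy's `default_rng`, so a fixed seed reproduces
cohorts bit for bit on any platform.

## Preprocessing conventions

Stage order (recorded in provenance): drop 5 volumes → motion-trace
alignment → linear detrend → nuisance + spike regression → band-pass →
masked smoothing.

- **FD**: Power's convention — sum of absolute backward differences, with
  rotations converted to arc length on a 50 mm sphere; FD[0] = 0. This is
  the dominant convention in the resting-state toolchain.
- **24 motion regressors**: parameters, one-frame lags (zero-padded first
  frame), and both sets squared.
- **CSF regressor**: mean of the dropped-and-detrended series inside the
  subject's CSF mask (probability ≥ 0.5). Extracting it after detrending is
  a documented choice; before/after detrending differs only by a line,
  which the design's intercept and the detrend absorb.
- **Spike regression**: one indicator column per FD > 1 mm frame. Because
  each indicator absorbs its frame exactly, residuals at spike frames are
  identically zero, and adding indicators to an intercept-only design
  leaves the correlation of the remaining frames unchanged (tested).
- **Rank deficiency**: collinear design columns are dropped via pivoted QR
  with a logged warning; residuals stay orthogonal to the retained columns.
- **Band-pass**: ideal rectangular filter on the discrete Fourier bins,
  keeping frequencies in [0.01, 0.1] Hz inclusive and zeroing the rest
  (DC included). Deterministic, phase-free, standard in this toolchain; it
  requires high < Nyquist = 1/(2·TR) ≈ 0.227 Hz at TR 2.2 s, checked before
  any computation.
- **Masked smoothing**: smooth(data·mask)/smooth(mask) with a Gaussian of
  4 mm FWHM (σ = FWHM/2.355 voxels), evaluated inside the mask and zero
  outside; denominator values < 1e−6 map to 0. Values outside the mask can
  never influence values inside (tested), and constants are preserved
  exactly. The truncation radius is scipy's int(4σ + 0.5); the brute-force
  oracle in the tests uses the same radius, where the kernel normalization
  cancels.

## Statistics

- **ANOVA**: per voxel, partial F for the group factor in the GLM
  y ~ intercept + group dummies + age + sex(M=1) + education, df =
  (g−1, n−g−c). With no covariates this reduces exactly to classical
  one-way ANOVA (tested against a hand-computed table and scipy). F
  p-values are upper-tail — the natural one-sided reading of an F test.
- **FDR**: Benjamini–Hochberg step-up, implemented directly and tested
  against both brute-force enumeration (all m ≤ 12) and statsmodels.
- **Post-hoc**: covariate-adjusted two-sample t on the group indicator,
  two-tailed, significant iff p < 0.05/m. m is an explicit parameter
  (defaults 6 for the GM family, 9 for the WM and DTI families) because the
  family size depends on how many ROIs the ANOVA stage yields.
- **Clusters**: 26-connectivity by default (configurable 6/18/26); no
  extent threshold; size = voxel count × voxel volume (always divisible by
  27 mm³ at 3 mm); peak = max |stat|; exactly mirrored components merge
  into one bilateral record with a ±x peak coordinate. Coordinates are mm
  from the grid centre, so the midline is x = 0.

## DTI

Log-linear least squares on ln S = ln S0 − b·gᵀDg, requiring ≥ 6
non-collinear weighted directions plus a b=0 volume; exact on noiseless
signals (machine precision, tested, including under random tensor
rotations). Non-positive signals are clamped to 1e−12 with a QA flag.
AD = λ₁ (the standard reading of axial diffusivity), MD = mean eigenvalue,
FA = sqrt(3/2)·‖λ − MD‖/‖λ‖ ∈ [0, 1]; slightly negative eigenvalues from
noise are clamped to 0 with the all-zero tensor assigned FA = 0. Weighted
or nonlinear estimators would add robustness on noisy data but cannot beat
exactness on the noiseless phantom; the simplest defensible estimator was
chosen.

## Classification

The t-test filter (keep a feature iff all three pairwise p < 0.05) and the
unit-variance scaling both use **training rows only**; validation rows are
transformed with training statistics (leakage is explicitly tested). The
"unit variance" scaling also centres — harmless for a linear SVM with bias
and numerically kinder. The cost grid is 2^e for e ∈ {−8, −7.75, …, 3}
(45 values), read as a log2 grid with exponent step 0.25; C is chosen by
stratified 5-fold CV accuracy with a fixed seed, ties going to the smallest
C. The model is LIBSVM's one-vs-one linear SVM (via scikit-learn), trained
once and applied unchanged to the validation cohort. Never-predicted
classes get precision 0 with a flag.

## What the phantom tests do and do not show

Passing tests establish that the pipeline's numerics are correct (oracle
agreement), that planted homotopic correlations are recovered without bias
beyond finite-sample effects, that detection localizes to the parcel
carrying the effect, and that the classification plumbing is sound and
leakage-free. They do **not** establish performance on real data: the
phantom has no hemodynamic convolution, no spatial autocorrelation outside
parcels, no scanner artifacts, no registration error, and its
between-subject variability is purely sampling noise (BOLD) or a small
eigenvalue jitter (DWI). The phantom SVM reaching 100% validation accuracy
reflects the large planted effects, not expected clinical performance.

Two measurement conventions matter when interpreting recovery numbers:

- Recovery of atanh(ρ_eff) is measured on **unsmoothed** maps (the chain up
  to and including the band-pass). Masked smoothing mixes parcel-border
  voxels with uncorrelated surround — a deterministic partial-volume
  attenuation of the parcel mean that is a property of smoothing, not an
  estimator defect. The full chain including smoothing must still, and
  does, deliver the strict NC > VMCI > MCI ordering.
- Sample Fisher z carries a small positive finite-sample bias
  (≈ ρ/2 per effective degree of freedom, a few 1e−3 here, enlarged by the
  band-pass reducing the effective sample size). Group means therefore sit
  within ~3 empirical SEM of the target rather than arbitrarily close.

## Problem sizes

Default cohorts are desk-scale: 10/10/10 training and 6/6/6 validation
subjects on the 24×28×24 grid — large enough that the planted effects are
detected with wide margins, small enough that the full pipeline runs in
about two minutes on one CPU. The acceptance script uses the same sizes;
tests use 2–8 subjects per group and shorter series where a property does
not need power.
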