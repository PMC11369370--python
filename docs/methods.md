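# Methods

## Problem setting

Diffuse reflectance spectroscopy (DRS) measures the wavelength-resolved
fraction of broadband light that re-emerges from tissue after scattering and
absorption. Because tumor and benign tissue differ in chromophore content
(hemoglobin, water, lipid, collagen) and in scattering, the shape of the
reflectance spectrum carries a tissue-type signal that can be exploited for
intraoperative margin assessment. This package implements the full analysis
chain for a two-spectrometer ex-vivo prostate-style study design: spectral
calibration and stitching, per-spectrum normalization, feature engineering
from class mean spectra, ReliefF feature selection, and repeated
patient-wise evaluation of a linear support-vector classifier — together
with a synthetic cohort generator so that every stage is testable without
access to clinical measurements.

## Spectral preprocessing

**Calibration.** Raw detector counts S(λ) are converted to reflectance with
white (Spectralon) and dark references, R = (S − D)/(W − D). This is the
universal DRS convention; a wavelength where W − D ≤ 0 has no usable
dynamic range and is treated as an error rather than silently clipped.
Calibration is scale-invariant: a common gain applied to S, W and D cancels.

**Stitching.** The visible channel (up to 1160 nm) and the NIR channel
(from 900 nm) are joined on the canonical grid — 400 to 1600 nm at 1 nm,
endpoint-inclusive, exactly 1201 points. Inside the 900–1160 nm overlap the
default policy is a linear cross-fade (visible weight falling 1 → 0 across
the overlap), which guarantees continuity without inventing a gain-matching
step; a hard cut at a configurable splice wavelength is available as an
alternative. How the vendor software actually reconciles the two
spectrometers is not documented anywhere we could rely on, so the
cross-fade is a declared design choice, not a reconstruction.

**Resampling** is plain linear interpolation; no smoothing is applied at
this stage. Requests outside the source span are errors, never
extrapolations.

**Normalization.** Each spectrum is standard-normal-variate (SNV)
transformed: z(λ) = (x(λ) − mean x)/sd x with the sample SD (n − 1
divisor). SNV removes per-measurement gain and offset (probe contact,
source drift) and is idempotent and invariant under positive affine maps of
the input. The sample-SD convention keeps the textbook example
[1, 2, 3] → [−1, 0, 1] exact. SNV is computed over the full 400–1600 nm
range; restricting it to a sub-range would be a one-line config change but
is not the default.

## Feature engineering

With 1201 wavelengths and on the order of 10² labeled measurements,
wavelength-wise classification overfits. Features are therefore derived
from the *class mean spectra* of the training split only:

1. each class mean is smoothed with a centered moving average
   (default window 15 nm) and its local minima/maxima with topographic
   prominence ≥ 0.05 (SNV units) become **landmarks** (grid endpoints are
   never landmarks);
2. landmarks from both classes are pooled and deduplicated;
3. **slope pairs** are formed from consecutive landmark wavelengths plus
   each minimum paired with its flanking maxima, dropping pairs closer than
   20 nm (near-degenerate difference quotients), ordered lexicographically
   and optionally truncated.

Every measurement is then scored: a landmark feature is the normalized
intensity at that wavelength; a slope feature is
(z(λ₂) − z(λ₁))/(λ₂ − λ₁) per nm. The smoothing window and prominence
threshold are free parameters of the method; the defaults were chosen so
that the water (970/1190/1450 nm) and lipid (930/1210 nm) band extrema
survive realistic instrument noise, and both are exposed in the
configuration. The pairing rule itself is one reasonable instantiation of
"slopes between wavelength pairs" rather than a canonical algorithm, and is
documented as such. On the default synthetic cohort the candidate set is
~30–40 features, comfortably larger than the 20 kept by selection.

## ReliefF feature selection

ReliefF is implemented from scratch (it is the analytical core here, and no
dependency in the stack provides it). For each instance i the k nearest
hits (same class) and k nearest misses (other class) are found under
Manhattan distance on min-max-scaled features, and each feature's weight is
updated by

    W[f] ← W[f] − Σ_hits diff(f,i,h)/(m·k) + Σ_misses diff(f,i,m′)/(m·k),

with diff(f,a,b) = |x_af − x_bf|/(max_f − min_f). All weights lie in
[−1, 1]; a constant feature has diff ≡ 0 and weight exactly 0. Defaults:
k = 10 neighbors (clamped to smallest-class − 1 with a warning), every
instance sampled (m = ALL), which together with row-order tie-breaking on
neighbor distances makes the ranking fully deterministic. Seeded
subsampling of instances is available but not the default. Top-k selection
(default k = 20) breaks equal-weight ties by feature declaration order so
repeated runs emit identical feature specs. Min-max scaling uses the table
the ranking sees — inside the evaluation loop that is the training fold
only.

The test suite checks the implementation against an independent exhaustive
brute-force oracle (plain Python loops over every hit/miss pair) with exact
agreement on small tables, plus symmetry (duplicated columns score
identically) and sign behavior (cleanly separating features score positive,
noise concentrates near zero).

## Classifier and evaluation protocol

Measurements from one patient share physiology and acquisition session, so
all splitting is **patient-wise**: round(0.70 · n_patients) patients train,
the rest test, and every measurement inherits its patient's side. Splits
that leave a class absent from either side are redrawn (bounded retries).

Per iteration, the entire analysis is re-derived from the training split —
class profiles, feature spec, ReliefF ranking, top-20 selection, feature
standardization, classifier fit — so no statistic of the test patients can
leak into the model. (Whether the original protocol re-derived features per
split or froze them once is not documented; re-derivation is the
leakage-safe reading and is what we implement.) The classifier is a linear
support-vector machine (hinge loss, L2 penalty); C is chosen from
{0.01, 0.1, 1, 10, 100} by mean stratified 10-fold cross-validated accuracy
within the training measurements (ties favor the smaller C), then refit on
the full training split. Features are standardized with training-split
statistics stored in the model.

Evaluation on the held-out patients reports, per iteration:

* sensitivity, specificity and accuracy at the classifier's **native
  threshold 0** (tumor = positive class);
* a threshold-free ROC built by sweeping the decision value, trapezoidal
  AUC, and the decision-value cutoff maximizing Youden J = sens + spec − 1.

The headline metrics use threshold 0 and the Youden-optimal cutoff is
reported alongside, because protocols of this kind rarely state which
threshold produced their quoted operating point. The default protocol runs
10 independent splits and reports mean ± sample SD (n − 1) per metric; with
a single iteration the SD is reported as 0 by convention.

## Synthetic cohort generator

The generator emulates the *statistical structure* of an ex-vivo prostate
DRS study, not prostate optics quantitatively:

* **Chromophores.** Five fixed, version-stamped extinction templates built
  from sums of Gaussians at the canonical band positions — hemoglobin
  Soret/Q bands (415/542/576 nm oxy, 430/555/760 nm deoxy), water
  970/1190/1450 nm, lipid 930/1210 nm, a broad collagen background. These
  are synthetic stand-ins in relative units, not literature coefficients.
* **Forward model.** A diffusion-style analytic surrogate
  R(λ) = S·exp(−μ_eff·ρ)/ρ² with μ_eff = √(3 μ_a (μ_a + μ_s′)),
  μ_s′ = a (λ/500)^(−b), ρ = 2 mm. It is smooth, strictly decreasing in
  μ_a, and carries the band structure into the spectra; it is *not* the
  full diffusion-theory expression and makes no claim of radiometric
  accuracy.
* **Cohort structure.** 59 patients, 5–10 measurements each; each
  measurement is tumor with probability 0.53; a Gaussian patient effect
  (SD 0.06 on concentrations, shared by a patient's measurements, so
  patients can contribute both classes as in the emulated study),
  within-patient jitter (SD 0.03), multiplicative (2%) and additive
  (2 × 10⁻⁴) instrument noise; a fraction 152/542 ≈ 0.28 of measurements
  keeps its label, the rest become "unlabeled" (uncertain histology) and
  are excluded from analysis while the ground-truth table retains them.
* **Class contrast.** Tumor = more blood and water, less lipid, slightly
  more collagen, scaled by a separation parameter δ ∈ [0, 1] (δ = 0 makes
  the classes identically distributed). This direction is a modeling
  assumption adopted to give the classes distinguishable band structure; it
  is not a measured prostate contrast. With the defaults (δ = 1) the
  classification problem is deliberately easy — the point is signal
  *recovery*, not realism of the achievable AUC.
* An optional two-channel mode simulates the visible and NIR spectrometers
  on their own grids with independent noise and runs them through the real
  stitching code.

What passing tests therefore show: the pipeline recovers class structure
when it exists (mean AUC ≥ 0.9 at default separation), sits at chance when
it does not (mean AUC ≈ 0.5 at δ = 0), responds monotonically to effect
size, and leaks nothing from test patients. What they do not show: that any
particular clinical accuracy is attainable on real prostate spectra — the
generator does not reproduce real biological variability, Gleason-grade
effects, heterogeneous measurement volumes or literature extinction curves.

## Numerical and reproducibility choices

* All ranges are physical nm and endpoint-inclusive; the canonical grid is
  constructed so "1201 wavelengths" holds exactly.
* Sample SD (ddof = 1) everywhere a spread is reported.
* Summary percentages round half-up to integers (clinical-table style), so
  80/152 and 72/152 display as 53 and 47.
* One base seed fans out to per-iteration seeds via a fixed affine-modular
  scheme (kept below 2³¹), so any single iteration can be reproduced in
  isolation; given config + seed, report files are byte-identical across
  runs.
* Degenerate inputs fail loudly: constant spectra (SNV), single-class
  tables (ReliefF, SVM, evaluation), non-overlapping channels (stitching),
  off-grid feature wavelengths, unknown YAML config keys.
* Problem sizes in the test suite and acceptance script: the study-shaped
  cohort (59 patients, ≈ 430 measurements, ≈ 135 labeled), 10-iteration
  evaluations, 20 iterations for the null calibration, and a 3 × 10-seed
  grid for the separation-monotonicity property — sizes at which the whole
  suite completes in about a minute on one CPU.

## Known limitations

* The slope-pair rule and the extrema-detection parameters are declared
  reconstructions of a loosely specified feature-engineering tradition;
  other defensible instantiations exist.
* ReliefF is the binary Kononenko form; multi-class prior weighting,
  RReliefF and SURF-family variants are out of scope.
* The forward model ignores photon-path effects beyond the μ_eff
  exponential; absolute reflectance levels are arbitrary (SNV removes them
  anyway).
* Class imbalance handling, probability calibration and nonlinear kernels
  are deliberately absent.
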