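# Methods

This note documents the models implemented in `restbrain`, the defaults
and why they were chosen, what the synthetic phantoms do and do not
emulate, and the numerical decisions that shape the results.

## Data model

All images live on regular grids with voxel spacing in mm and a 4×4
grid-to-world affine (0-based voxel indices, RAS-oriented by default).
NIfTI-1 single-file I/O goes through nibabel; the TR of a 4D series is
carried in pixdim[4]. Gaussian smoothing uses σ = FWHM / (2√(2 ln 2))
per axis, scaled by spacing, with reflective padding so the image mean
is conserved on small phantoms (no edge darkening).

## Phantoms

Generators are pure functions of (parameters, seed); every bundle
carries the exact ground truth it was built from, and the forward models
used for generation (dipole convolution, tensor signal equation) are the
same operators the reconstruction code inverts, so closed-loop recovery
tests are meaningful.

- **Structural**: an ellipsoidal bright "brain" (intensity 1), a dark
  CSF gap (0.05), and a bright skull/scalp shell (0.8) on the functional
  grid (64×64×33 at 3.75×3.75×4 mm), plus Gaussian noise. Contrast is 1,
  so CNR = 1/noise_sd. The CSF gap and shell are present only on slices
  that contain brain: a closed ellipsoidal shell would produce filled
  bright caps beyond the brain poles, which no per-slice contour method
  could distinguish from brain, and an imaged slab with lateral skull is
  also the more realistic geometry.
- **BOLD**: 33 slices × 210 time points at TR 2 s (6,930 2D slice
  images per run). Voxel noise is AR(1) (lag-1 coefficient 0.3 by
  default, in the range typical of resting BOLD); spherical "activity"
  blobs share a common slow signal (sum of sinusoids in 0.01–0.08 Hz)
  with a blend fraction f: voxel = (1−f)·own-noise + f·shared.
- **DWI**: S = S₀ exp(−b gᵀDg) over 25 approximately uniform
  (Fibonacci-hemisphere) directions at b = 1,000 s/mm², acquired twice,
  plus two b = 0 volumes — 52 volumes over 35 slices (1,820 slice
  images). The printed protocol does not uniquely determine the volume
  structure; 25×2+2 is the decomposition consistent with the slice
  total, and the scheme is fully parameterizable. Optional Rician noise
  at a given SNR.
- **Susceptibility**: spheres of constant χ (defaults 0.10 and
  0.05 ppm) inside a spherical brain mask; background sources outside
  the mask generate a field that is harmonic within it (computed on a
  padded grid so the source truly lies outside the FOV interior). The
  field-to-phase scale is exposed (default 16 rad/ppm ≈ 3 T at
  TE 20 ms); output phase is wrapped to (−π, π].
- **Group maps**: per-subject Gaussian random fields smoothed to a
  target FWHM (default 6 mm) and standardized to unit variance within an
  ellipsoidal analysis mask; group A means are shifted by Cohen's d
  inside spherical effect blobs. Cohort sizes default to 100 vs 20.

None of the phantoms have realistic anatomy, motion, susceptibility
texture, or physiological noise. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under their stated model
assumptions, not performance on clinical data.

## Brain extraction

A closed polygon of N = 64 vertices per axial slice, initialized as a
circle of radius r₀/m (m = 2) about the intensity centroid of the
above-threshold foreground, where r₀ is the equivalent radius of the
foreground area. Because thin bright shells (skull/scalp) would inflate
r₀ and shift the start point outside the brain, initialization keeps the
largest connected component of the 2-pixel-eroded foreground (restored
by dilation) — the contour model assumes its starting circle lies inside
brain tissue.

Per vertex with neighbors A₁, A₂ and midpoint A_C, s = A_C − A₀ is split
into tangential s_t and normal s_n components:

- tension u₁ = s_t keeps vertex spacing even;
- smoothing u₂ = s_n · ½(1 + tanh(F(1/r − E))) with local curvature
  radius r = l²/(2|s_n|), E = (1/r_min + 1/r_max)/2,
  F = 6/(1/r_min + 1/r_max). The bounded tanh step is used because the
  printed tan form of this force is unbounded and singular at r = E,
  which contradicts its role of gentle curvature limiting;
- expansion u₃ along the surface normal with magnitude
  2(I_min − t₁)/(I_max − t₂): I_min and I_max are searched inward over
  d₁ = 7 mm and d₂ = 14 mm, t₂ is 0.02 of the robust (2nd–98th
  percentile) intensity range, and t₁ = t₂ + b_t(I_max − t₂) with
  b_t = 0.5. The sign convention pushes outward while the inward minimum
  stays above t₁ and reverses once the vertex overshoots into dark
  background, so the resultant force vanishes at the tissue edge.

Updates are synchronous with damping 0.5, stopping when the largest
damped displacement falls below 0.01 px or after 500 iterations; a
polygon collapsing below 3 px² raises an error. Volume masks are built
by even-odd rasterization of the converged polygons. Slices whose
initial disk is not bright (median below t₂ + 0.25·range, thresholds
taken from the whole volume) yield empty planes — with no inter-slice
regularization, this is the per-slice analogue of "the circle starts
inside the brain". On the structural phantom at CNR 20 the resulting
mask reaches Dice ≈ 0.99 against truth.

## Registration

The affine stage maximizes global CC with Nelder–Mead simplex restarts
over (translation, rotation) or the full 12-parameter set (plus
log-scales and shears), coarse-to-fine over a 3-level pyramid
(subsampling 4/2/1 after matched smoothing). Rotations act about the
fixed-image center so translations stay decoupled. The returned
transform never scores below the identity; on failure the identity is
returned with a warning flag. Trilinear interpolation is the default,
nearest-neighbor for masks; resampling uses continuous zero padding
("grid-constant"), because hard cut-off padding creates discontinuities
at the field of view edge that corrupt gradient-driven refinement.

The nonlinear stage is a small-deformation fluid scheme sharing the CC
objective: both images are standardized within the mask, which makes
the sum-of-squared-differences a strictly decreasing function of CC, and
per-voxel demons-normalized forces d·∇m/(|∇m|² + d²/s²) are smoothed
with a Gaussian (fluid regularization, default 6 mm), applied with steps
capped at 0.4 voxel, followed by a light 1 mm smoothing of the
accumulated field (elastic regularization). Steps that do not increase
CC halve the step size. The Jacobian determinant of (I + ∇u) is
monitored; the run aborts if the positive fraction over the mask drops
below 99 %, standing in for a diffeomorphic guarantee at desk scale.
A raw global-CC gradient was tried first and rejected: at phantom scale
it suffers a severe aperture problem (CC → 0.99 with a displacement
field unrelated to the truth). Note that the tangential (level-set)
component of any displacement field is invisible to intensity matching,
so recovery tests use a radially structured phantom in which the applied
radial deformation is identifiable.

## QSM

1. **Laplacian unwrapping**: ∇²φ = cos φ ∇² sin φ − sin φ ∇² cos φ with
   all Laplacians evaluated spectrally, then division by −4π²k² with the
   k = 0 coefficient set to zero (the mean phase is not recoverable; the
   undefined leading factor in the printed combined formula is read as
   the plain spectral inverse). Exact up to a harmonic component, which
   the next stage absorbs. The discrete trig nonlinearity aliases
   slightly, so the fixed-point property under re-application holds to
   ~1e-6 RMS only for gently varying phase.
2. **V-SHARP background removal**: φ' = φ − S⊗φ with spherical-mean
   kernels whose radius shrinks from 6 voxels to 1 toward the mask edge
   (mask-compensated means, radius schedule chosen since no parameters
   are given in the source description), followed by deconvolution with
   K = FT⁻¹[FT(S)/(1 − FT(S))] of the largest kernel, truncating
   frequencies where |1 − FT(S)| < 0.05. Output is restricted to the
   1-voxel-eroded reliable region.
3. **Dipole inversion**: minimize ‖M(s·F⁻¹DFχ − φ_nh)‖² + λ‖W∇χ‖₁ with
   D(k) = 1/3 − (k·b₀)²/|k|², D(0) = 0, unit gradient weights by
   default, and the L1 term smoothed by ε = 1e-6 so each outer IRLS
   iteration is a linear least-squares problem solved by LSQR (60 inner
   iterations, 5 outer; the outer objective is monitored and
   non-increasing). χ is **supported on the mask**: solving on the full
   grid would let the minimal-norm solution park source energy outside
   the mask where the field is unobserved, biasing tissue χ low by
   ~20 % on the sphere phantom; with the support constraint the closed
   loop recovers sphere means within ~5–15 % and in-mask correlation
   ≥ 0.90 at 64³ (noiseless, λ = 0).

## ReHo

Slice-timing correction shifts each slice's series to the reference
slice's acquisition time by linear temporal interpolation (held
endpoints). Motion QC excludes a subject if any volume exceeds 1.5 mm
translation or 1.5° rotation, with strict inequality at the boundary.
The band-pass is a zero-phase frequency-domain mask retaining
0.01–0.08 Hz (the resting-state convention: keep slow fluctuations,
remove drift and high frequencies) and removes the series mean.

Kendall's W ranks each series over time with midranks for ties and uses
W = 12 Σ_t (R_t − R̄)² / (k²(n³ − n)); no tie-correction term is applied
(ties have measure zero in float data, and the independent brute-force
oracle uses the same convention). The ReHo map computes W over each
in-mask voxel and its 26 neighbors (27-, 19-, and 7-voxel neighborhoods
supported), dropping neighbors outside mask or grid and zeroing voxels
with fewer than two series. The implementation is vectorized: per-voxel
temporal midranks are summed over the neighborhood by 3D convolution
per time point, which is algebraically identical to the direct formula
(verified voxel-by-voxel to 1e-12). Standardization divides by the
whole-mask mean (mask mean exactly 1), then 6 mm smoothing; smoothing
follows standardization, matching the listed processing order.

## DTI

Log-linear least squares of ln S = ln S₀ − b gᵀDg per voxel (signals
floored at 1e-8 before the log), requiring ≥ 6 unique directions plus
b = 0; a rank check rejects collinear schemes. Eigenvalues are clipped
at zero before computing MD = (λ₁+λ₂+λ₃)/3 and
FA = √(3/2)·‖λ − MD‖/‖λ‖, keeping FA ∈ [0, 1] under noise. The
log-linear fit is the default because it is deterministic and exactly
testable; no weighting or nonlinear refinement is applied.

## Metrics

RMSE is the root mean square voxel difference. HFEN is
‖LoG(x) − LoG(y)‖²_F / ‖LoG(x)‖²_F with a 15³-support, σ = 1.5 voxel
Laplacian-of-Gaussian kernel (the HFEN literature convention), averaged
over supplied image pairs; the first argument is the reference, making
the metric deliberately asymmetric. SSIM uses the standard global form
(2μ_xμ_y + c₁)(2σ_xy + c₂) / ((μ_x² + μ_y² + c₁)(σ_x² + σ_y² + c₂))
with c₁ = (0.01L)², c₂ = (0.03L)², L the reference dynamic range; the
covariance term carries the factor 2 required for SSIM(x, x) = 1. A
sliding-window mode (mean of local SSIM over a boxcar window) is
available behind a flag.

## Cluster statistics

Voxelwise pooled-variance two-sample t-tests (df = n_a + n_b − 2);
zero-variance voxels are flagged undefined rather than zeroed. The
AlphaSim-style correction simulates null Gaussian fields on the mask
grid, smooths them to the assumed FWHM (supplied explicitly, not
estimated from residuals), standardizes within the mask, applies the
two-sided voxel threshold, and records the maximum cluster extent per
iteration; the returned extent is the smallest k with empirical
P(max ≥ k) ≤ α. Defaults: two-sided voxel p = 0.005, α = 0.05, 1,000
iterations, 6-connectivity (18/26 configurable). Cluster tables report
peak |t| voxels mapped to world mm, extent, direction, and the corrected
flag, and are written as TSV. Because extent is integer-valued, the
attained family-wise error at the returned k may sit strictly below α
while k − 1 overshoots; the calibration tests check exactly this
sandwich property. With d = 0 group maps at the default cohort sizes
(100 vs 20), the observed family-wise error over 20 seeded repetitions
is 0.05 at α = 0.05.

## Pipeline

`restbrain run config.yaml` validates the config (referenced files are
checked before any compute), generates or loads inputs, executes the
enabled stages in dependency order, and writes each output with a JSON
sidecar carrying stage parameters, package version, and seed. One global
seed fans out to per-stage seeds by CRC-32 hashing of the stage name, so
stochastic stages are independent yet bit-reproducible; outputs are
write-once per run directory.

## Problem sizes and runtime

Tests and the acceptance script run at the sizes the phantoms define:
BOLD/structural at 64×64×33, QSM at 64³, DTI recovery on an 8×8×4
tensor field with the full 52-volume scheme, registration recovery at
48×48×32, group calibration on 20 repetitions of 120 subject maps with
500 Monte-Carlo null fields. The full suite runs in about a minute and
the acceptance script in well under a minute on one CPU.

## Known limitations

- The per-slice contour has no inter-slice regularization; mask borders
  can disagree by a voxel between adjacent slices, and slices where the
  brain cross-section is smaller than the initial circle are skipped.
- Laplacian unwrapping assumes periodic images; strong phase gradients
  at the FOV boundary leak ringing into the interior (absorbed here by
  the background-removal stage).
- V-SHARP deconvolution uses the largest kernel only; near-edge voxels
  filtered with smaller radii are deconvolved approximately.
- The nonlinear registration is small-deformation; large deformations
  would require a proper diffeomorphic (geodesic) formulation.
- The Monte-Carlo correction assumes the supplied smoothness and
  Gaussian one-sample statistics for the null fields; t-statistics with
  very small groups have heavier tails than the simulated z fields.
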