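# Methods

This note documents the models, estimators, defaults and numerical
choices behind `jmoct`, and what the synthetic validation does and does
not demonstrate about real tissue data.

## Forward model of the phantom generator

Each depth pixel of a layer is a linear retarder with single-pass
retardation `η = 2π Δn Δz / λ₀` at orientation `θ` (axis in the Q–U
plane).  The cumulative single-pass matrix is the ordered product
`J_cum(z) = J(z) … J(1) J(0)`, and the measured round-trip matrix uses
the reciprocal transpose-symmetric form `J_cum(z)ᵀ J_cum(z)`, so the
round-trip retardation per pixel is twice the single-pass value.  This
makes the δ ↔ Δn conversion of the birefringence estimator exactly
testable: a homogeneous layer of birefringence Δn must be recovered as
Δn for any depth separation (modulo π-wrapping).

**Speckle.** Fully developed speckle multiplies each voxel's matrix by a
circular complex Gaussian amplitude with mean power
`R · exp(−2 ∫ µ dz)`, where R is the layer reflectivity and the optical
depth accumulates through all overlying layers (Beer–Lambert,
single-scatter).  The attenuation estimator is scale invariant, so only
the decay rate matters.

**Polarization scrambling.** Depolarization is modelled as a random
SU(2) element applied per voxel, obtained by geodesic interpolation
(quaternion slerp) between the identity and a Haar-uniform random
rotation with mixing weight `s ∈ [0, 1]`.  The slerp of the identity
toward a Haar rotation with half-angle Ω produces a rotation by `2sΩ`
about a uniformly random axis, which gives the closed-form ensemble DOPU

    κ(s) = 1/3 + (2/3)·sinc(s) − (1/3)·[sinc(1+s) + sinc(1−s)]

(normalized sinc), with κ(0) = 1 and κ(1) = 0; `expected_dopu` exposes it
and a Monte-Carlo property test verifies it.  At s = 1 the output states
are isotropic on the Poincaré sphere, the regime in which the DOPU
estimator must follow the mean-resultant-length law of uniform unit
vectors.  The random element is applied on the left of the round-trip
matrix; this deliberately breaks transpose symmetry, since depolarization
is not a reciprocal unitary process.  The scrambling index is a
phenomenological mixing weight, not calibrated to any particular tissue.

**Noise.** Additive complex white Gaussian noise per matrix entry, scaled
so the mean surface-voxel intensity exceeds the per-voxel noise intensity
by `snr_db`.  A linear sensitivity roll-off in dB/mm is available
(default off) to mimic spectrometer-based systems.

**What the phantoms do not model:** multiple scattering, depth-dependent
focus/beam shape, axial point-spread convolution, motion, refraction at
tissue interfaces, and any quantitative tumor-tissue optical model.
Passing the recovery tests therefore demonstrates correctness of the
estimators under their own assumptions, not clinical performance.

## Attenuation

`µ(i) = I(i) / (2Δ Σ_{j>i} I(j))` assumes the beam is fully attenuated
within the recorded depth and that the backscattered fraction is
proportional to µ.  No tail extrapolation is performed; the deepest pixel
(empty tail) is NaN.  Two documented biases:

* **Discretization**: on an exact discrete exponential the estimator
  returns `(e^{2µΔ} − 1)/(2Δ)` (≈ +0.7% at µ = 1 mm⁻¹, Δ = 7.24 µm;
  ≈ +6% at µ = 8 mm⁻¹).  `debias=True` applies the exact inversion
  `µ = ln(1 + 2Δµ_raw)/(2Δ)`.
* **Tail truncation**: near the bottom of the recorded range the missing
  tail inflates the estimate by a relative `≈ e^{−2µ(D−z)}`.  Recovery
  studies therefore evaluate depth pixels `[4, 0.75·N)` of an N = 1024
  pixel phantom; with 64-A-scan lateral averaging the median relative
  error is ≈ 8% for µ ∈ {1, 4, 8} mm⁻¹, dominated by residual speckle
  (relative intensity s.d. 1/√64).

## Local birefringence and its reliability

The local matrix `L(z) = J(z+d) J(z)⁻¹` (default depth separation d = 2
pixels) is diagnosed only through its eigenvalue phase difference,
wrapped to [0, π]; eigenvectors are never used, making the estimate
invariant to any static unitary pre-/post-multiplication by the system.
`Δn = δ λ₀ / (4π d Δz)`; the equivalent deg/µm conversion is
`δ/(2 d Δz)·(180/π)` for round-trip retardation per physical depth.

Pixels with singular `J(z)` or intensity below the supplied noise floor
are NaN with reliability 0.

**Naive estimator** returns the raw eigen-phase difference.  Because δ is
folded into [0, π], noise biases it upward, most strongly near δ = 0.
Its reliability output is a monotone local-SNR heuristic
`SNR/(SNR+10)` (1.0 for noiseless input) — a ranking device, not a
posterior probability.

**MAP estimator**: the observed eigen-phase distribution given a true
retardation is tabulated by seeded Monte-Carlo (default 256-point
retardation grid on [0, π], 2000 draws per grid point, 128 observation
bins, per 3-dB local-SNR bin) for `L = (A·R(δ) + N₂)(A·I + N₁)⁻¹` with
complex Gaussian noise of unit per-entry power and `A² = 2·SNR`.  With a
flat prior the posterior over the grid is the likelihood row of the
observed bin; the estimator returns the posterior mode, and reliability
is the posterior mass within 0.1 rad of the mode.  This is an
approximation built from the declared noise model, validated by its
bias-reduction property (at 20 dB SNR and δ = 0 the MAP mean is well
below the naive mean), not by identity with any specific published
derivation.  Tables are cached per SNR bin; the smoothing constant 0.5
added to histogram counts prevents zero-likelihood bins.

At finite SNR the naive estimator's bias means measured Δn values sit
above ground truth, and polarization scrambling adds apparent
retardation; two-group comparisons (both groups measured identically)
retain the correct effect direction, which is what the end-to-end test
asserts.  Interpreting absolute birefringence in strongly depolarizing
regions is unreliable — a known limitation of the contrast itself.

## DOPU

Per incident channel (Jones matrix column), normalized Stokes components
`(Q, U, V)/I` with `Q = |Eh|² − |Ev|²`, `U = 2Re(Eh Ev*)`,
`V = −2Im(Eh Ev*)` are averaged over a kernel of default 3 (axial) × 5
(lateral) pixels — chosen to span several speckles at 7.24 µm axial /
~12 µm lateral pitch, and config-exposed since no canonical value
exists.  Zero-intensity voxels are excluded from the kernel mean
(masked average); kernels at the volume border use nearest-neighbour
extension, so quantitative comparisons against the finite-n
mean-resultant-length law are made on interior kernels.  The output is
the mean of the two channel DOPUs, clipped to [0, 1].  For orthogonal
incident states the channel Stokes vectors are antipodal, so both
channels carry the same resultant length.

## SD-OCT reconstruction

The chain is applied in a fixed order: cubic-spline resampling to a
uniform k grid (linear interpolation available), Gaussian window
(default FWHM = half the sampled band, centered on the middle of the
band — a data-independent center, so any spectrum component common to
all A-lines is cancelled exactly by the later mean subtraction),
multiplication by `exp(−i[a₂(k−k₀)² + a₃(k−k₀)³])` with known
coefficients (dispersion calibration from data is out of scope),
subtraction of the across-A-line mean, FFT, positive-frequency |·|².
The depth pitch is `π / (k span)`; zero-padding (`pad_factor`) refines
the sampling for FWHM measurements without changing resolution.  The
fringe generator randomizes each reflector's phase per A-line (speckle),
so mean subtraction removes the DC term rather than the signal.

## Mosaicking

Registration is plain phase correlation of en-face mean projections with
the argmax restricted to a window around the stage-expected offset;
confidence is the ratio of the in-window peak to the second candidate.
Offsets are integer pixels; the global layout chains consecutive pairs in
acquisition order (no global least-squares).  The search margin must be
small enough that the window does not wrap past the tile period —
ambiguity appears when `expected + margin` approaches the tile size.
Feather blending uses border-distance ramp weights normalized to sum to
one at every pixel, so constant overlapping tiles reproduce the constant
exactly; a single tile is returned verbatim.  One lateral layout is
applied to all contrast channels.

## Statistics

Mann–Whitney U uses midrank ties; the two-sided p is exact (full
enumeration of rank assignments) for tie-free pooled samples of at most
16 values and otherwise the tie-corrected normal approximation with
continuity correction.  Degenerate all-equal input returns p = 1.  The
suite checks exactness against an independent enumeration oracle and the
type-I error rate at α = 0.05 over 2000 null replicates (n = 20 per
group) against the binomial 99% interval.  Levene's test is the classic
mean-centered variant (median-centered Brown–Forsythe available).  Box
summaries use linearly interpolated quartiles and 1.5·IQR whiskers
placed on data points — for very small samples with an extreme outlier
the whisker can land inside the interpolated box, which is why the
invariant asserted is whisker_lo ≤ median ≤ whisker_hi.  No
multiple-testing correction is applied across contrasts.

## Tumor/control dataset defaults

Control region: muscle-like, Δn = 1.8·10⁻³, scrambling 0.3,
µ = 2.0 mm⁻¹.  Tumor shifts: Δn −1.0·10⁻³, scrambling −0.2,
µ +1.0 mm⁻¹; SNR 25 dB; 32 B-scans of 128 (z) × 64 (x) voxels, regions
split left/right with a lateral guard band wider than the DOPU kernel
and masks confined to the upper 75% of depth (away from the
attenuation tail bias).  These effect sizes are plausible soft-tissue
values chosen once for the validation study; they are free parameters of
the generator, not calibrated to any measured tissue.

## Problem sizes of the validation runs

Attenuation recovery uses 1024 × 256 phantoms (4 groups of 64 averaged
A-scans); birefringence bias uses ~2000 pixels at 20 dB; the DOPU
isotropic check uses > 10⁴ interior kernels against a 2·10⁴-draw
sphere-sampling oracle; SD-OCT uses 1024-sample spectra; stitching uses
512-px tiles at 5% (26 px) overlap and a three-tile 64 × 160 strip.
These sizes give stable statistics while keeping the full suite and the
acceptance script in the tens of seconds.
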