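# Methods

This note documents the models, numerical choices and limitations of
`muracam` in enough detail to reproduce or audit any number the package
computes.

## Mask patterns and decoding

The basic MURA pattern of prime rank *p* is built from quadratic
residues modulo *p*: cell (i, j) is open iff i ≠ 0 and (j = 0 or the
residue characters of i and j agree). It has exactly (p² − 1)/2 open
cells and row 0 closed. The signed decoding array is +1 on open cells,
−1 on closed ones, with element (0, 0) forced to +1. With this
convention the circular cross-correlation of the periodically tiled
pattern with the decoder is a single integer peak of height (p² − 1)/2
on *exactly zero* sidelobes — the tests assert integer equality, not a
tolerance.

The physical mask is the no-two-holes-touching (NTHT) variant — the
basic pattern spread onto a doubled grid with 0.08 mm round holes at
open cells — duplicated in a plain 2×2 mosaic. The stated mask side of
9.92 mm (124 cells × 0.08 mm) confirms plain duplication rather than a
cyclic (2p−1)-style mosaic. The two-holes-touching (THT) idealization
collapses the NTHT grid back to contiguous full cells of the basic
pattern at 0.16 mm pitch; the MLEM system PSF uses THT to avoid the
periodic background ripple the sparse NTHT holes would imprint on the
correlation operators.

## PSF rasterization

A PSF at distance z is the mask mosaic magnified by M(z) = 1 + b/z and
projected, centered, onto the detector grid; pixel values are open-area
fractions computed by k×k point supersampling per detector pixel
(default k = 8; doubling k changes no pixel by more than 0.04).
Detector pixel centers sit at (i + 0.5 − N/2) × pitch, so the pattern
center falls on the geometric detector center (between pixels for the
even 256-pixel grid); reconstructions of a centered source therefore
peak within one pixel of the image center. Rasterized PSFs are
normalized to unit sum before entering any forward model, so that
source intensities mean *expected detected quanta* and the (1−t)/t
split of the transmission model is meaningful.

## Forward simulation

Sources are small Gaussian blobs (0.65 mm FWHM by default, matching
the physical test source) rendered on the source-plane grid of their
distance, forward-projected through the NTHT PSF with the transmission
model, summed, and optionally Poisson-sampled from a single
`numpy.random.default_rng(seed)` generator. Slice grids are in
projection orientation (world +x maps to −x), which makes the
convolutional forward model exact: a one-pixel slice shift moves the
shadow one detector pixel, equivalently a source shift of Δx mm moves
the shadow centroid by Δx·b/z mm.

The tungsten linear attenuation coefficient at 59.5 keV ships as the
constant 7.06 mm⁻¹ (≈ 3.66 cm²/g × 19.3 g/cm³, standard tabulations),
giving t = exp(−μ·0.11 mm) ≈ 0.46 for the default mask. Transmission
is treated as angle-independent; septal penetration and collimation
artifacts of the thin mask are not modeled.

The default simulated intensity of 10⁶ expected quanta puts ~15 counts
in an average pixel — a realistic photon-counting regime; the absolute
scale only matters through the Poisson noise level, since the CNR is
invariant under affine intensity rescaling.

## MURA Decoding

Decoding extracts the centered square window onto which one basic
pattern projects — side = basic side × M(z) in pixels, rounded half
away from zero — and circularly cross-correlates it with the decoding
array resampled to the window grid by nearest-neighbor lookup (each
window pixel maps through the projection back to a mask cell, which
preserves the ±1 balance). The operation runs in the frequency domain;
a brute-force rolling-sum oracle checks it in the tests. The window
must fit the detector, which bounds decodable distances below by
b / (detector_side/basic_side − 1) ≈ 10.88 mm for the default camera.
Negative reconstruction values are kept; the CNR machinery only uses
relative values. Stacks can be resized by bilinear interpolation to the
slice at the reference (true source) distance; resized and non-resized
stacks give axial FWHMs compatible within their fit uncertainties.

## 3D-MLEM

Each slice f_z updates multiplicatively:

    f_z ← (f_z / n_z) · [ h_z ⋆ ( max(p − Σ_{z'≠z} F(f_z', h_z'), 0)
                                  / (F(f_z, h_z) + ε) ) ]

with n_z = h_z ⋆ 1 (the back-projection of a fully illuminated
detector), ε = 10⁻¹²  on all divisions, and negative residuals clamped
to zero so slices stay non-negative. Forward convolution and the
back-projection are exact adjoints, implemented with one cached kernel
FFT on a zero-padded grid (no unintended circular wrap-around). The
printed denominator form F(f∗h) is read as F(f_z, h_z): with that
reading the exact-data fixed point holds (ratio ≡ 1 back-projects to
n_z and slices do not move).

Slices are swept sequentially (Gauss–Seidel): each update sees the
freshest forward projections of the other slices, with the summed
forward projection maintained incrementally. A simultaneous (Jacobi)
sweep is unstable for this update — the subtract-other-slices numerator
over-corrects any total-count mismatch by roughly the number of slices,
and with residual clamping the all-zero state is absorbing — whereas
the sequential sweep converges, keeps the single-slice Poisson
log-likelihood non-decreasing (tested to 10⁻⁸ relative per step), and
recovers the source depth.

Initialization is a uniform positive constant per slice scaled so the
total forward counts match the data; 40 iterations are the default
working point. Without transmission the converged forward projection
reproduces the detector counts to ≲0.1 % (this is what n_z ensures);
with t = 0.46 the uniform background component converges more slowly
(~3 % count excess after 40 iterations, ~1 % after 150), which does not
affect the CNR-based resolution measures. The original update variant
(summed-PSF normalization, no transmission term) is retained for
comparison only. Input images are used in their native energy units; no
division by the photon energy is applied.

For sources beyond ~40 mm the 2×2 mosaic's self-similarity can create
regular ghost maxima near the image border; the assessment restricts
the signal search to the central half of the image area and flags
stacks whose border region outshines the central signal.

## Resolution assessment

* ROI diameter: the 0.65 mm source FWHM divided by the reconstruction
  pixel footprint FOV(z)/side at the true distance, rounded to the
  nearest integer (≥1). FOV is detector_side·z/b for full-detector
  (MLEM/pinhole) reconstructions and basic_side·z/b for MURA windows
  (the latter convention is configuration-injectable, as published FOV
  formulas for MURA decoding vary).
* ROIs are circular (pixels whose centers fall inside the disc of the
  bounding box), sampled at every fully-contained placement —
  (side − d + 1)² positions, ~19 000 for a 150-px MURA slice with
  d = 13 and ~62 000 for a 256-px MLEM slice with d = 8.
* The signal is the brightest ROI whose center lies in the centered
  square of half the image *area* (side/√2); ties break to the lowest
  row, then column, with a warning. ROIs whose discs overlap the signal
  (center distance < d) are excluded; all others are background. σ̄_B is
  the mean of per-ROI standard deviations (the alternative — the std of
  background pixel values — is selectable in principle but not default).
* Positions are frozen on the in-focus slice; for non-resized MURA
  stacks they are rescaled to each slice's grid.
* The offset-Gaussian fit uses `scipy.optimize.curve_fit` with
  α₀ = min CNR, β₀ = max CNR, γ₀ = argmax z, δ₀ = span/6, δ bounded
  positive. Monte-Carlo (100 draws of 5 % amplitude noise on 60
  samples) keeps the fitted peak within 0.15 mm of truth.
* Fine stacks use 0.5 mm steps centered on the true distance when it is
  known (the reference procedure), otherwise on a coarse 5–100 mm /
  5 mm localization. Half-spans default to 20 mm (MURA) and 8 mm
  (MLEM); the study-condition experiments use 25/14 mm, matching the
  60–240 (MURA) and 54–101 (MLEM) slice counts of measured-data stacks.
  Too narrow a span under-constrains the fit offset and biases γ.

## What the synthetic generator does and does not capture

The generator reproduces the geometry, source size, mask transmission
and Poisson counting statistics of the experiment. It does **not**
model detector physics (charge sharing, energy response, defective
pixels), tissue scatter, angle-dependent mask penetration, or extended
sources. Consequences observed with this package: simulated noiseless
data make MURA Decoding's CNR denominator purely numerical, so at
close range its axial profile is *sharper* than MLEM's — the measured
ordering (MLEM roughly 3× sharper axially) emerges only under counting
noise, and the acceptance suite therefore checks depth recovery on
noiseless data but the method ordering on noisy data. Absolute
simulated FWHMs are somewhat smaller than measured hardware values;
orderings, trends with distance, and the CNR machinery itself transfer.

## Preprocessing

Measured images are cleaned before reconstruction: pixels strictly
outside the [1st, 99th] percentile band (≤2 % of pixels) are replaced
by their 3×3 neighborhood median, then a σ = 1 px Gaussian smoothing is
applied. Constant images pass through unchanged.

## Known limitations

* The axial assessment assumes a single dominant point-like source.
* MURA decoding cannot reconstruct planes closer than ~10.9 mm
  (geometry-bound); MLEM has no such bound but slows linearly with the
  number of slices.
* Runtime: MURA decodes a slice in ~1 ms; MLEM needs two FFT
  convolutions per slice per iteration (~0.4 s per slice for 40
  iterations at 256²).
* The measured 21-image dataset is not bundled; tests that regress
  against it run only when a local copy is present.
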