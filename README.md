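# muracam

A toolkit for near-field coded-aperture gamma-camera imaging: it
simulates detector images of point-like gamma sources seen through a
MURA mask, reconstructs depth stacks with two methods (MURA Decoding
and a transmission-aware 3D-MLEM), and measures the camera's axial and
lateral resolution from contrast-to-noise-ratio (CNR) profiles.

It is written for researchers working on compact gamma cameras for
intraoperative nuclear medicine (e.g. sentinel-lymph-node localization),
where a coded aperture offers high sensitivity and — uniquely among
collimators — depth information from a single 2D exposure.

## The camera and the model

The modeled camera is a 256×256-pixel photon-counting detector
(14.08×14.08 mm²) behind a rank-31 *no-two-holes-touching* (NTHT) MURA
mask: 0.08 mm round holes in a 0.11 mm tungsten sheet, duplicated in a
2×2 mosaic (9.92×9.92 mm² total) at a detector-to-mask distance
*b* = 20 mm. A point source at distance *z* in front of the mask casts
a mask shadow magnified by

    M(z) = 1 + b / z

so the shadow's size encodes depth and its shift encodes lateral
position. At 59.5 keV about *t* ≈ 46 % of photons penetrate the thin
tungsten sheet; this transmission is modeled as a uniform background,
giving the forward projection of a source plane *f_z* through the PSF
*h_z* (the magnified mask pattern):

    F(f_z, h_z) = (1 − t) (f_z ∗ h_z) + t Σ f_z / N²

Two reconstructions are implemented:

* **MURA Decoding** — the exact inverse filter of the periodic mask
  pattern: the central detector window covered by one basic pattern is
  circularly convolved with the signed decoding array resampled to the
  in-focus magnification. Fast (milliseconds per plane) but each plane
  is reconstructed independently, which blurs depth.
* **3D-MLEM** — a convolutional maximum-likelihood EM algorithm that
  reconstructs all depth planes jointly, extended with a per-slice
  sensitivity map *n_z = h_z ⋆ 1* (the mask is smaller than the
  detector, so off-axis shadows partly miss it) and the transmission
  forward model above. Slower, but far lower background and a much
  sharper depth response.

Resolution is assessed the way an experimentalist would: reconstruct an
image stack in 0.5 mm depth steps, sample every placement of a circular
ROI sized to the source (0.65 mm FWHM) on the in-focus slice, take the
brightest central ROI as signal and all non-overlapping ROIs as
background, compute CNR(z) = (S̄ − B̄)/σ̄_B per slice, and fit
CNR(z) = α + (β − α) exp(−(z − γ)²/2δ²). The axial resolution is
FWHM = 2√(2 ln 2) δ ≈ 2.35 δ; the lateral resolution is the same fit
along the brightest image row, converted to mm via the field of view.

## Worked example

```python
from muracam import (CameraGeometry, SourceScene, simulate_detector_image,
                     assess_axial, magnification)

geometry = CameraGeometry()          # the experimental camera: b = 20 mm, rank-31 NTHT mask
scene = SourceScene(sources=[(0.0, 0.0, 30.0, 1e6)])   # centered source, 30 mm away
image = simulate_detector_image(scene, geometry, seed=7, noisy=True)

print(f"magnification M(30 mm) = {magnification(geometry, 30.0):.2f}")
for method in ("mura", "mlem"):
    res = assess_axial(image, geometry, method, truth_z_mm=30.0)
    print(f"{method:4s}: axial FWHM = {res.axial_fwhm_mm:.2f} +/- "
          f"{res.axial_fwhm_std_mm:.2f} mm, peak at z = {res.fitted_z_mm:.2f} mm, "
          f"lateral FWHM = {res.lateral_fwhm_mm:.2f} mm")
```

prints

```
magnification M(30 mm) = 1.67
mura: axial FWHM = 9.27 +/- 0.33 mm, peak at z = 30.60 mm, lateral FWHM = 0.44 mm
mlem: axial FWHM = 2.40 +/- 0.04 mm, peak at z = 30.08 mm, lateral FWHM = 0.34 mm
```

Both methods locate the source depth to well within a millimeter of the
true 30 mm; the iterative reconstruction resolves depth about four
times more sharply than the inverse filter, at roughly 50× the compute
cost. Simulated (idealized) images give somewhat sharper axial FWHMs
than measured hardware data, but the same ordering and degradation with
distance.

The same pipeline is available from the shell:

```bash
muracam simulate --z 30 --intensity 1e6 --seed 7 --out sim30.txt
muracam assess   --image sim30.txt --method mlem --truth-z 30 --out result.csv
muracam decode   --image sim30.txt --z-min 15 --z-max 45 --z-step 5 --out stack.tif
muracam mlem     --image sim30.txt --z-min 25 --z-max 35 --z-step 0.5 --out mlem.tif
```

Measured detector images (plain-text matrices or TIFF) can be assessed
the same way; `muracam fetch-data --source <dir>` catalogs a local copy
of the published 21-distance measurement set.

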