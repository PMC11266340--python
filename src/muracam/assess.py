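"""Axial and lateral resolution assessment from CNR profiles.

The axial resolution of the camera is measured from an image stack
(reconstructions of one detector image at successive depths):

1. A circular ROI diameter is derived from the physical source size
   (0.65 mm FWHM) and the reconstruction FOV at the true distance.
2. Every possible ROI position is sampled on the in-focus slice; the
   ROI with the highest mean inside the inner 50% of the image area is
   the signal, ROIs overlapping it are discarded, all others are
   background.  ROI positions are then frozen across the stack.
3. Per slice, CNR = (S_mean - B_mean) / B_std where B_mean / B_std are
   the averages of the background ROI means / standard deviations.
4. A Gaussian with offset, CNR(z) = a + (b - a) exp(-(z - g)^2 / 2 d^2),
   is fitted to the profile; the axial FWHM is 2 sqrt(2 ln 2) d.

The lateral resolution is the FWHM of a 1D Gaussian-with-offset fit to
the in-focus slice row through the brightest pixel, converted to mm via
the FOV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve

from .decoding import decode_stack
from .geometry import CameraGeometry, central_part_side, fov, min_decodable_z
from .mlem import reconstruct_3d
from .simulate import DetectorImage
from .stacks import ImageStack

__all__ = [
    "FWHM_PER_SIGMA",
    "RoiTable",
    "CnrProfile",
    "ResolutionResult",
    "preprocess",
    "roi_diameter",
    "sample_rois",
    "select_signal_roi",
    "cnr",
    "cnr_profile",
    "fit_cnr_profile",
    "assess_axial",
    "assess_lateral",
]

#: FWHM of a Gaussian per unit standard deviation, 2 sqrt(2 ln 2) ~ 2.35.
FWHM_PER_SIGMA = float(2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(raw: DetectorImage | np.ndarray) -> DetectorImage:
    """Outlier replacement and smoothing of a raw detector image.

    Pixels strictly below the 1st or strictly above the 99th percentile
    are replaced by the median of their 3x3 neighborhood, then the image
    is smoothed with a Gaussian of sigma = 1 pixel.
    """
    meta = dict(raw.meta) if isinstance(raw, DetectorImage) else {}
    pixels = raw.pixels if isinstance(raw, DetectorImage) else np.asarray(raw, float)
    lo, hi = np.percentile(pixels, [1.0, 99.0])
    median = ndimage.median_filter(pixels, size=3, mode="reflect")
    cleaned = np.where((pixels < lo) | (pixels > hi), median, pixels)
    smoothed = ndimage.gaussian_filter(cleaned, sigma=1.0)
    meta["preprocessed"] = True
    return DetectorImage(pixels=np.clip(smoothed, 0.0, None), meta=meta)


# ---------------------------------------------------------------------------
# ROI machinery

def roi_diameter(
    geometry: CameraGeometry,
    z_mm: float,
    method: str,
    source_fwhm_mm: float = 0.65,
    image_side_px: int | None = None,
) -> int:
    """ROI diameter in pixels: the source FWHM at the reconstruction scale.

    The source FWHM is divided by the pixel footprint FOV(z)/side of the
    reconstruction at the true source distance and rounded to the
    nearest integer (clamped to >= 1).
    """
    if method in ("mura",):
        fov_mm = fov(geometry, z_mm, "mura")
        side = image_side_px or central_part_side(geometry, z_mm)
    elif method in ("mlem", "pinhole"):
        fov_mm = fov(geometry, z_mm, "pinhole")
        side = image_side_px or geometry.detector_pixels
    else:
        raise ValueError(f"unknown method {method!r}")
    d = int(np.floor(source_fwhm_mm / (fov_mm / side) + 0.5))
    if d < 1:
        warnings.warn(
            f"source FWHM spans less than half a pixel at z = {z_mm} mm; "
            "clamping ROI diameter to 1 px"
        )
        d = 1
    return d


def disc_kernel(diameter: int) -> np.ndarray:
    """Boolean disc: pixels whose centers fall within the bounding-box circle."""
    if diameter < 1:
        raise ValueError("ROI diameter must be >= 1")
    off = np.arange(diameter) - (diameter - 1) / 2.0
    return (off[:, None] ** 2 + off[None, :] ** 2) <= (diameter / 2.0) ** 2


@dataclass
class RoiTable:
    """Mean and standard deviation of every circular ROI placement.

    Placements are dense: every position where the ROI bounding box is
    fully inside the image, i.e. (side - d + 1)^2 of them.  ``means``
    and ``stds`` are 2D arrays indexed by the bounding-box top-left
    corner.
    """

    means: np.ndarray
    stds: np.ndarray
    diameter: int
    image_side_px: int

    @property
    def n_positions(self) -> int:
        return self.means.size

    def center(self, i: int, j: int) -> tuple[float, float]:
        """Pixel-center coordinates of the ROI at placement (i, j)."""
        half = (self.diameter - 1) / 2.0
        return (i + half, j + half)

    def to_frame(self) -> pd.DataFrame:
        m = self.means.shape[0]
        ii, jj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        half = (self.diameter - 1) / 2.0
        return pd.DataFrame({
            "center_row": ii.ravel() + half,
            "center_col": jj.ravel() + half,
            "mean": self.means.ravel(),
            "std": self.stds.ravel(),
        })


def sample_rois(image: np.ndarray, diameter: int) -> RoiTable:
    """Sample every fully-contained placement of a circular ROI."""
    image = np.asarray(image, dtype=float)
    side = image.shape[0]
    if diameter > side:
        raise ValueError(
            f"ROI diameter {diameter} exceeds image side {side}"
        )
    disc = disc_kernel(diameter).astype(float)
    npix = disc.sum()
    mean = fftconvolve(image, disc, mode="valid") / npix
    mean_sq = fftconvolve(image * image, disc, mode="valid") / npix
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return RoiTable(means=mean, stds=np.sqrt(var), diameter=diameter,
                    image_side_px=side)


@dataclass
class SignalSelection:
    """Frozen signal ROI placement and the background placement mask."""

    position: tuple[int, int]       # bounding-box top-left indices
    background: np.ndarray          # bool over all placements
    diameter: int


def select_signal_roi(table: RoiTable, central_fraction: float = 0.5) -> SignalSelection:
    """Pick the brightest ROI within the inner ``central_fraction`` of the area.

    The central region is the centered square holding that fraction of
    the image area (side / sqrt(2) for the default 50%), which avoids
    selecting ghost sources along the image border.  ROIs overlapping
    the signal are excluded from the background set.
    """
    m = table.means.shape[0]
    half = (table.diameter - 1) / 2.0
    centers = np.arange(m) + half
    img_center = (table.image_side_px - 1) / 2.0
    half_side = table.image_side_px * np.sqrt(central_fraction) / 2.0
    allowed_1d = np.abs(centers - img_center) <= half_side
    allowed = allowed_1d[:, None] & allowed_1d[None, :]
    if not allowed.any():
        raise ValueError("no ROI placement lies within the central region")
    masked = np.where(allowed, table.means, -np.inf)
    flat = int(np.argmax(masked))  # row-major: lowest row then column on ties
    pi, pj = divmod(flat, m)
    if np.count_nonzero(masked == masked[pi, pj]) > 1:
        warnings.warn("multiple equal signal maxima; picked the first in "
                      "row-major order")
    # exclude placements whose disc overlaps the signal disc
    ii, jj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    dist2 = (ii - pi) ** 2 + (jj - pj) ** 2
    background = dist2 >= table.diameter ** 2
    return SignalSelection(position=(pi, pj), background=background,
                           diameter=table.diameter)


def cnr(signal_mean: float, background_means, background_stds) -> float:
    """Contrast-to-noise ratio (S_mean - B_mean) / B_std.

    ``B_mean`` is the average of the background ROI means and ``B_std``
    the average of the background ROI standard deviations.
    """
    background_means = np.asarray(background_means, dtype=float)
    background_stds = np.asarray(background_stds, dtype=float)
    if background_means.size == 0:
        raise ValueError("at least one background ROI is required")
    sigma = float(background_stds.mean())
    if sigma == 0:
        raise ValueError("degenerate background: zero average standard deviation")
    return float((signal_mean - background_means.mean()) / sigma)


def cnr_profile(
    stack: ImageStack,
    diameter: int,
    in_focus_index: int,
    central_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, SignalSelection]:
    """CNR of every slice with ROI positions frozen on the in-focus slice.

    For non-resized stacks whose slice sizes differ (MURA Decoding), the
    frozen signal position is rescaled to each slice's pixel grid before
    the CNR is read off.
    """
    ref_side = stack[in_focus_index].side_px
    table0 = sample_rois(stack[in_focus_index].pixels, diameter)
    sel = select_signal_roi(table0, central_fraction)
    pi, pj = sel.position
    half = (diameter - 1) / 2.0
    values = np.empty(len(stack))
    for k, s in enumerate(stack.slices):
        if k == in_focus_index:
            table = table0
        else:
            table = sample_rois(s.pixels, diameter)
        if s.side_px == ref_side:
            qi, qj, bg = pi, pj, None
        else:
            scale = s.side_px / ref_side
            m = table.means.shape[0]
            qi = int(np.clip(round((pi + half + 0.5) * scale - 0.5 - half),
                             0, m - 1))
            qj = int(np.clip(round((pj + half + 0.5) * scale - 0.5 - half),
                             0, m - 1))
            ii, jj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
            bg = (ii - qi) ** 2 + (jj - qj) ** 2 >= diameter ** 2
        mask = sel.background if bg is None else bg
        values[k] = cnr(table.means[qi, qj],
                        table.means[mask], table.stds[mask])
    return stack.z_values, values, sel


# ---------------------------------------------------------------------------
# profile fitting

def _gauss_offset(z, alpha, beta, gamma, delta):
    return alpha + (beta - alpha) * np.exp(-((z - gamma) ** 2) / (2.0 * delta ** 2))


@dataclass
class CnrProfile:
    """A fitted CNR(z) profile: samples, parameters and derived FWHM."""

    z_mm: np.ndarray
    cnr: np.ndarray
    params: tuple[float, float, float, float]   # alpha, beta, gamma, delta
    cov: np.ndarray
    fwhm_mm: float
    fwhm_std_mm: float

    @property
    def peak_z_mm(self) -> float:
        return self.params[2]


def fit_cnr_profile(z_mm, cnr_values) -> CnrProfile:
    """Least-squares fit of the offset Gaussian to a CNR profile.

    FWHM = 2 sqrt(2 ln 2) * delta with its standard deviation propagated
    from the delta covariance entry.
    """
    z = np.asarray(z_mm, dtype=float)
    y = np.asarray(cnr_values, dtype=float)
    if z.size < 5:
        raise ValueError("need at least 5 CNR samples spanning the peak")
    span = z.max() - z.min()
    p0 = [float(y.min()), float(y.max()), float(z[np.argmax(y)]), span / 6.0]
    bounds = ([-np.inf, -np.inf, z.min() - span, 1e-9],
              [np.inf, np.inf, z.max() + span, np.inf])
    try:
        params, cov = curve_fit(_gauss_offset, z, y, p0=p0, bounds=bounds,
                                maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"CNR profile fit did not converge (initial guess {p0}); "
            f"residual range [{y.min():.3g}, {y.max():.3g}]"
        ) from exc
    delta = params[3]
    fwhm = FWHM_PER_SIGMA * delta
    fwhm_std = FWHM_PER_SIGMA * float(np.sqrt(np.abs(cov[3, 3])))
    return CnrProfile(z_mm=z, cnr=y, params=tuple(params), cov=cov,
                      fwhm_mm=float(fwhm), fwhm_std_mm=fwhm_std)


# ---------------------------------------------------------------------------
# end-to-end assessment

@dataclass
class ResolutionResult:
    """Axial (and optionally lateral) resolution of one detector image."""

    method: str
    source_z_mm: float
    axial_fwhm_mm: float
    axial_fwhm_std_mm: float
    fitted_z_mm: float
    roi_diameter_px: int
    profile: CnrProfile
    lateral_fwhm_mm: float | None = None
    ghost_flag: bool = False
    preprocessed: bool = False
    meta: dict = field(default_factory=dict)


def _fine_grid(z0: float, span: float, step: float, z_min: float) -> np.ndarray:
    lo = max(z0 - span, z_min)
    n_lo = int(round((z0 - lo) / step))
    n_hi = int(round(span / step))
    return z0 + step * np.arange(-n_lo, n_hi + 1)


def locate_source_coarse(
    image: DetectorImage,
    geometry: CameraGeometry,
    method: str,
    z_grid_mm=None,
    iterations: int = 40,
) -> float:
    """Coarse localization: z of the slice with the highest per-slice CNR.

    Reconstructs over a broad grid (default 5-100 mm in 5 mm steps,
    clipped to the decodable range for MURA Decoding) and re-runs the
    signal search independently on every slice.
    """
    if z_grid_mm is None:
        z_grid_mm = np.arange(5.0, 100.1, 5.0)
    z_grid = np.asarray(z_grid_mm, dtype=float)
    if method == "mura":
        z_grid = z_grid[z_grid >= min_decodable_z(geometry)]
        stack = decode_stack(image, geometry, z_grid, resize=False)
    elif method == "mlem":
        stack = reconstruct_3d(image, geometry, z_grid, iterations=iterations)
    else:
        raise ValueError(f"unknown method {method!r}")
    best_z, best_cnr = None, -np.inf
    for s in stack.slices:
        d = roi_diameter(geometry, s.z_mm, method, image_side_px=s.side_px)
        table = sample_rois(s.pixels, d)
        sel = select_signal_roi(table)
        value = cnr(table.means[sel.position],
                    table.means[sel.background], table.stds[sel.background])
        if value > best_cnr:
            best_z, best_cnr = s.z_mm, value
    return float(best_z)


def _detect_ghosts(table: RoiTable, sel: SignalSelection,
                   central_fraction: float = 0.5) -> bool:
    """Flag when some border-region ROI outshines the central signal."""
    m = table.means.shape[0]
    half = (table.diameter - 1) / 2.0
    centers = np.arange(m) + half
    img_center = (table.image_side_px - 1) / 2.0
    half_side = table.image_side_px * np.sqrt(central_fraction) / 2.0
    outside_1d = np.abs(centers - img_center) > half_side
    outside = outside_1d[:, None] | outside_1d[None, :]
    if not outside.any():
        return False
    return bool(table.means[outside].max() > table.means[sel.position])


def assess_axial(
    image: DetectorImage,
    geometry: CameraGeometry,
    method: str,
    truth_z_mm: float | None = None,
    fine_step_mm: float = 0.5,
    fine_span_mm: float | None = None,
    iterations: int = 40,
    resize: bool = True,
    with_lateral: bool = True,
    central_fraction: float = 0.5,
) -> ResolutionResult:
    """Measure the axial (and lateral) resolution of one detector image.

    When ``truth_z_mm`` is given the fine stack is centered on it (the
    reference procedure for measured data with a known source position);
    otherwise a coarse 5-100 mm / 5 mm localization stage estimates the
    center first.  ``fine_span_mm`` defaults to 20 mm for MURA Decoding
    (whose profiles are wide) and 8 mm for MLEM.
    """
    if method not in ("mura", "mlem"):
        raise ValueError(f"unknown method {method!r}")
    z0 = (float(truth_z_mm) if truth_z_mm is not None
          else locate_source_coarse(image, geometry, method,
                                    iterations=iterations))
    if fine_span_mm is None:
        fine_span_mm = 20.0 if method == "mura" else 8.0
    z_min = (min_decodable_z(geometry) + fine_step_mm if method == "mura"
             else max(fine_step_mm, 2.0))
    z_grid = _fine_grid(z0, fine_span_mm, fine_step_mm, z_min)

    if method == "mura":
        stack = decode_stack(image, geometry, z_grid, resize=resize,
                             reference_z_mm=z0)
    else:
        stack = reconstruct_3d(image, geometry, z_grid, iterations=iterations)

    in_focus = stack.nearest_index(z0)
    side = stack[in_focus].side_px
    d = roi_diameter(geometry, z0, method, image_side_px=side)
    z, values, sel = cnr_profile(stack, d, in_focus,
                                 central_fraction=central_fraction)
    profile = fit_cnr_profile(z, values)
    ghost = _detect_ghosts(sample_rois(stack[in_focus].pixels, d), sel,
                           central_fraction)
    lateral = None
    if with_lateral:
        fov_mm = fov(geometry, z0, "mura" if method == "mura" else "pinhole")
        try:
            lateral = assess_lateral(stack[in_focus].pixels, fov_mm)
        except RuntimeError:
            lateral = None
    return ResolutionResult(
        method=method,
        source_z_mm=z0,
        axial_fwhm_mm=profile.fwhm_mm,
        axial_fwhm_std_mm=profile.fwhm_std_mm,
        fitted_z_mm=profile.peak_z_mm,
        roi_diameter_px=d,
        profile=profile,
        lateral_fwhm_mm=lateral,
        ghost_flag=ghost,
        preprocessed=bool(image.meta.get("preprocessed", False)),
        meta={
            "fine_step_mm": fine_step_mm,
            "fine_span_mm": fine_span_mm,
            "n_slices": len(stack),
            "signal_position": sel.position,
            "truth_z_mm": truth_z_mm,
        },
    )


def assess_lateral(in_focus: np.ndarray, fov_mm: float) -> float:
    """Lateral FWHM (mm) from the in-focus slice row through the peak."""
    img = np.asarray(in_focus, dtype=float)
    row_idx = int(np.unravel_index(np.argmax(img), img.shape)[0])
    row = img[row_idx]
    x = np.arange(row.size, dtype=float)
    if np.ptp(row) == 0:
        raise RuntimeError("flat in-focus row; no peak to fit")
    p0 = [float(row.min()), float(row.max()), float(np.argmax(row)), 2.0]
    try:
        params, _ = curve_fit(_gauss_offset, x, row, p0=p0,
                              bounds=([-np.inf, -np.inf, 0, 1e-9],
                                      [np.inf, np.inf, row.size, row.size]),
                              maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError("lateral profile fit did not converge") from exc
    fwhm_px = FWHM_PER_SIGMA * params[3]
    return float(fwhm_px * fov_mm / row.size)
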