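"""Rasterized point-spread functions of the mask.

The PSF at distance ``z`` is the detector image of an ideal centered
point source: the mask mosaic magnified by M(z) = 1 + b/z and projected
onto the detector pixel grid.  Each pixel stores the fraction of its
area covered by open mask area (values in [0, 1]), computed by k x k
supersampling.

Two hole models are supported: ``NTHT`` renders the physical mask
(round holes of ``hole_diameter_mm`` in every other cell), which is
what measured detector images actually show; ``THT`` renders the
two-holes-touching idealization (contiguous full cells of the basic
pattern at doubled pitch), which the MLEM reconstruction uses as its
system PSF to avoid periodic background artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CameraGeometry, magnification
from .mask import MaskPattern

__all__ = ["PsfImage", "rasterize_psf"]


@dataclass(frozen=True)
class PsfImage:
    """Open-area-fraction image of the mask shadow for a source at ``z_mm``."""

    z_mm: float
    pixels: np.ndarray
    mode: str
    magnification: float

    @property
    def total(self) -> float:
        return float(self.pixels.sum())

    def normalized(self) -> np.ndarray:
        """PSF scaled to unit sum (detection pdf given passage through holes)."""
        s = self.pixels.sum()
        if s <= 0:
            raise ValueError("PSF has no open area on the detector")
        return self.pixels / s


def _supersample_coords(n: int, k: int, pitch: float) -> np.ndarray:
    """Physical coordinates (mm from detector center) of k subsamples/pixel."""
    return ((np.arange(n * k) + 0.5) / k - n / 2.0) * pitch


def rasterize_psf(
    geometry: CameraGeometry,
    pattern: MaskPattern,
    z_mm: float,
    mode: str = "NTHT",
    supersampling: int = 8,
) -> PsfImage:
    """Project the mask mosaic at magnification M(z) onto the detector grid.

    The mask center is projected onto the detector center.  Pixel values
    are open-area fractions obtained by ``supersampling`` x
    ``supersampling`` point sampling per detector pixel.
    """
    mode = mode.upper()
    if mode not in ("THT", "NTHT"):
        raise ValueError(f"mode must be 'THT' or 'NTHT', got {mode!r}")
    if supersampling < 1:
        raise ValueError("supersampling factor must be >= 1")
    m = magnification(geometry, z_mm)
    if geometry.mask_side_mm * m < geometry.pixel_pitch_mm:
        raise ValueError(
            f"magnified mask ({geometry.mask_side_mm * m:.3g} mm) is smaller "
            f"than one detector pixel at z = {z_mm} mm"
        )

    n = geometry.detector_pixels
    k = supersampling
    rank = pattern.rank
    # sample coordinates on the mask plane (divide detector coords by M)
    c = _supersample_coords(n, k, geometry.pixel_pitch_mm) / m

    if mode == "THT":
        pitch = geometry.tht_pitch_mm
        idx = np.floor(c / pitch).astype(np.int64)
        valid = (idx >= -rank) & (idx < rank)
        mod = np.mod(idx, rank)
        open_grid = pattern.basic[np.ix_(mod, mod)].astype(bool)
        open_grid &= valid[:, None] & valid[None, :]
    else:
        pitch = geometry.cell_pitch_mm
        side = 2 * rank
        idx = np.floor(c / pitch).astype(np.int64)
        valid = (idx >= -side) & (idx < side)
        mod = np.mod(idx, side)
        open_grid = pattern.ntht[np.ix_(mod, mod)].astype(bool)
        open_grid &= valid[:, None] & valid[None, :]
        # restrict to the round hole inscribed in each open cell
        off = c - (idx + 0.5) * pitch
        r2 = (geometry.hole_diameter_mm / 2.0) ** 2
        inside = (off[:, None] ** 2 + off[None, :] ** 2) <= r2
        open_grid &= inside

    frac = open_grid.reshape(n, k, n, k).mean(axis=(1, 3))
    return PsfImage(z_mm=float(z_mm), pixels=frac, mode=mode, magnification=m)
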