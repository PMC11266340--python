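"""MURA Decoding: inverse-filter reconstruction of in-focus planes.

Decoding extracts the central part of the detector image — the window
onto which exactly one basic mask pattern (a quarter of the 2x2 mosaic)
is projected at the chosen distance — and circularly cross-correlates
it with the signed decoding array resampled to the same pixel grid.
Because the mosaic is periodic, the window contains one full period and
the circular operation is exact; the MURA delta-correlation property
then collapses the overlapped shadows back to the source distribution.

The window size grows as the in-focus plane approaches the mask
(side = basic_side * M(z) in pixels), so slice sizes depend on z; a
stack can be resized to a common reference size by bilinear
interpolation.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft
from skimage.transform import resize as _sk_resize

from .geometry import CameraGeometry, central_part, magnification
from .mask import MaskPattern
from .simulate import DetectorImage
from .stacks import ImageStack, ReconSlice

__all__ = ["circular_correlate", "decoder_on_grid", "mura_decode", "decode_stack"]


def circular_correlate(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular cross-correlation out[k] = sum_x image[x + k] * kernel[x].

    Computed in the frequency domain; lags wrap periodically (zero lag
    at index 0).
    """
    image = np.asarray(image, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if image.shape != kernel.shape:
        raise ValueError("image and kernel must share a shape")
    return sp_fft.irfft2(
        sp_fft.rfft2(image) * np.conj(sp_fft.rfft2(kernel)), s=image.shape
    )


def decoder_on_grid(
    geometry: CameraGeometry,
    pattern: MaskPattern,
    z_mm: float,
    side_px: int,
) -> np.ndarray:
    """Resample the signed decoding array to a central-part pixel grid.

    Each window pixel is mapped through the magnified projection back to
    a mask cell (nearest-neighbor, THT cell pitch) and takes that cell's
    +-1 decoder value, preserving the +-1 balance of the array.
    """
    m = magnification(geometry, z_mm)
    # window pixel centers, mm from the window (= detector) center
    c = (np.arange(side_px) + 0.5 - side_px / 2.0) * geometry.pixel_pitch_mm
    cell = np.floor(c / m / geometry.tht_pitch_mm).astype(np.int64)
    idx = np.mod(cell, pattern.rank)
    return pattern.decoding[np.ix_(idx, idx)].astype(float)


def mura_decode(
    image: DetectorImage | np.ndarray,
    geometry: CameraGeometry,
    z_mm: float,
    pattern: MaskPattern | None = None,
) -> ReconSlice:
    """Decode one in-focus plane at distance ``z_mm``.

    Returns a slice in projection orientation whose center corresponds
    to the optical axis; a centered source reconstructs to a peak at
    pixel (side//2, side//2).
    """
    if pattern is None:
        pattern = MaskPattern.from_rank(geometry.rank)
    pixels = image.pixels if isinstance(image, DetectorImage) else np.asarray(image)
    window = central_part(geometry, pixels, z_mm)
    side = window.shape[0]
    dec = decoder_on_grid(geometry, pattern, z_mm, side)
    out = np.fft.fftshift(circular_correlate(window, dec))
    return ReconSlice(z_mm=float(z_mm), pixels=out)


def decode_stack(
    image: DetectorImage | np.ndarray,
    geometry: CameraGeometry,
    z_grid_mm,
    resize: bool = True,
    reference_z_mm: float | None = None,
    pattern: MaskPattern | None = None,
) -> ImageStack:
    """Decode a detector image at every distance of ``z_grid_mm``.

    Distances that are not decodable (central part larger than the
    detector) are collected in ``stack.failures`` rather than aborting
    the whole stack.  With ``resize=True`` all slices are bilinearly
    interpolated to the size of the slice nearest ``reference_z_mm``
    (default: the middle of the grid).
    """
    if pattern is None:
        pattern = MaskPattern.from_rank(geometry.rank)
    z_grid = [float(z) for z in np.atleast_1d(z_grid_mm)]
    slices: list[ReconSlice] = []
    failures: dict[float, str] = {}
    for z in z_grid:
        try:
            slices.append(mura_decode(image, geometry, z, pattern=pattern))
        except ValueError as exc:
            failures[z] = str(exc)
    if not slices:
        raise ValueError(
            f"no decodable distance in the grid; failures: {failures}"
        )
    if resize:
        zs = np.array([s.z_mm for s in slices])
        if reference_z_mm is None:
            reference_z_mm = float(np.median(zs))
        ref = slices[int(np.argmin(np.abs(zs - reference_z_mm)))]
        target = ref.side_px
        slices = [
            s if s.side_px == target else ReconSlice(
                z_mm=s.z_mm,
                pixels=_sk_resize(s.pixels, (target, target), order=1,
                                  preserve_range=True, anti_aliasing=False),
            )
            for s in slices
        ]
    return ImageStack(slices=slices, method="mura", resized=resize,
                      failures=failures,
                      meta={"reference_z_mm": reference_z_mm})
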