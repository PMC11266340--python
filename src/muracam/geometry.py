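"""Camera geometry: physical constants of the coded-aperture gamma camera.

The camera consists of a pixelated detector (256x256 pixels over
14.08x14.08 mm^2) and a rank-31 no-two-holes-touching (NTHT) MURA mask
duplicated in a 2x2 mosaic (9.92x9.92 mm^2), held at a fixed
detector-to-mask distance ``b``.  A point source at distance ``z`` in
front of the mask casts a shadow of the mask magnified by

    M(z) = 1 + b / z

so the shadow size encodes depth and the shadow shift encodes the
lateral position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from sympy import isprime

__all__ = [
    "CameraGeometry",
    "magnification",
    "fov",
    "central_part_side",
    "central_part",
    "min_decodable_z",
]

#: Linear attenuation coefficient of Tungsten at 59.5 keV, per mm
#: (~3.66 cm^2/g mass attenuation x 19.3 g/cm^3), standard tabulations.
MU_TUNGSTEN_59KEV_PER_MM = 7.06


@dataclass(frozen=True)
class CameraGeometry:
    """Physical constants of the camera.

    All lengths in mm.  Defaults describe the experimental camera:
    Timepix3 detector (14.08 mm side, 256 pixels) behind a rank-31 NTHT
    MURA mask with 0.08 mm round holes in a 0.11 mm Tungsten sheet at
    ``b_mm`` = 20 mm, imaging a 59.5 keV source.
    """

    detector_side_mm: float = 14.08
    detector_pixels: int = 256
    b_mm: float = 20.0
    rank: int = 31
    cell_pitch_mm: float = 0.08
    hole_diameter_mm: float = 0.08
    mask_thickness_mm: float = 0.11
    energy_kev: float = 59.5
    transmission_t: float = field(default=0.46)

    def __post_init__(self) -> None:
        if not isprime(self.rank):
            raise ValueError(f"mask rank must be prime, got {self.rank}")
        if not 0.0 <= self.transmission_t <= 1.0:
            raise ValueError(
                f"transmission_t must lie in [0, 1], got {self.transmission_t}"
            )
        for name in ("detector_side_mm", "b_mm", "cell_pitch_mm",
                     "hole_diameter_mm", "mask_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.detector_pixels < 1:
            raise ValueError("detector_pixels must be >= 1")

    # -- derived quantities -------------------------------------------------

    @property
    def pixel_pitch_mm(self) -> float:
        """Detector pixel pitch (detector side / number of pixels)."""
        return self.detector_side_mm / self.detector_pixels

    @property
    def tht_pitch_mm(self) -> float:
        """Cell pitch of the two-holes-touching (THT) pattern.

        The NTHT pattern places holes in every other cell, so collapsing
        it back to contiguous full cells doubles the pitch.
        """
        return 2.0 * self.cell_pitch_mm

    @property
    def basic_side_mm(self) -> float:
        """Physical side of one basic mask pattern (a quarter of the mosaic)."""
        return self.rank * self.tht_pitch_mm

    @property
    def mask_side_mm(self) -> float:
        """Physical side of the full 2x2 mask mosaic."""
        return 2.0 * self.basic_side_mm

    def to_dict(self) -> dict:
        return {
            "detector_side_mm": self.detector_side_mm,
            "detector_pixels": self.detector_pixels,
            "b_mm": self.b_mm,
            "rank": self.rank,
            "cell_pitch_mm": self.cell_pitch_mm,
            "hole_diameter_mm": self.hole_diameter_mm,
            "mask_thickness_mm": self.mask_thickness_mm,
            "energy_kev": self.energy_kev,
            "transmission_t": self.transmission_t,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraGeometry":
        known = {
            "detector_side_mm", "detector_pixels", "b_mm", "rank",
            "cell_pitch_mm", "hole_diameter_mm", "mask_thickness_mm",
            "energy_kev", "transmission_t",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(**d)


def magnification(geometry: CameraGeometry, z_mm: float) -> float:
    """Shadow magnification M = 1 + b/z for a source at distance ``z_mm``."""
    if z_mm <= 0:
        raise ValueError(f"source-to-mask distance must be positive, got {z_mm}")
    return 1.0 + geometry.b_mm / z_mm


def fov(geometry: CameraGeometry, z_mm: float, method: str = "pinhole") -> float:
    """Field of view (mm) of a reconstruction plane at distance ``z_mm``.

    ``method='pinhole'`` (used by the MLEM reconstruction, which keeps the
    full detector): FOV = detector_side * z / b.  ``method='mura'`` (used
    by MURA Decoding, which keeps only the central part covered by one
    basic pattern): FOV = basic_pattern_side * z / b.
    """
    if z_mm <= 0:
        raise ValueError(f"source-to-mask distance must be positive, got {z_mm}")
    if method == "pinhole":
        return geometry.detector_side_mm * z_mm / geometry.b_mm
    if method == "mura":
        return geometry.basic_side_mm * z_mm / geometry.b_mm
    raise ValueError(f"unknown FOV method {method!r}")


def central_part_side(geometry: CameraGeometry, z_mm: float) -> int:
    """Pixel side of the detector window covered by one projected basic pattern.

    The basic pattern (one quarter of the 2x2 mosaic) projects to
    ``basic_side_mm * M(z)`` on the detector; the window side is that
    length in pixels, rounded half away from zero.
    """
    m = magnification(geometry, z_mm)
    side_mm = geometry.basic_side_mm * m
    return int(math.floor(side_mm / geometry.pixel_pitch_mm + 0.5))


def min_decodable_z(geometry: CameraGeometry) -> float:
    """Smallest source-to-mask distance whose central part fits the detector.

    Solves basic_side * (1 + b/z) <= detector_side for z.  Below this
    distance the projected basic pattern is larger than the detector and
    MURA Decoding cannot extract a full period.
    """
    ratio = geometry.detector_side_mm / geometry.basic_side_mm - 1.0
    if ratio <= 0:
        return math.inf
    return geometry.b_mm / ratio


def central_part(geometry: CameraGeometry, image, z_mm: float):
    """Extract the centered square window onto which one basic pattern projects.

    Raises ``ValueError`` when the window would exceed the detector, which
    happens for sources closer than :func:`min_decodable_z`.
    """
    import numpy as np

    image = np.asarray(image)
    n = geometry.detector_pixels
    if image.shape != (n, n):
        raise ValueError(f"expected {n}x{n} detector image, got {image.shape}")
    side = central_part_side(geometry, z_mm)
    if side > n:
        raise ValueError(
            f"projected basic pattern ({side} px) exceeds the detector "
            f"({n} px) at z = {z_mm} mm; MURA decoding requires "
            f"z >= {min_decodable_z(geometry):.2f} mm"
        )
    start = (n - side) // 2
    return image[start:start + side, start:start + side]
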