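"""Reconstruction slices and z-stacks shared by both reconstruction methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReconSlice", "ImageStack"]


@dataclass
class ReconSlice:
    """One reconstructed in-focus plane at distance ``z_mm``.

    MURA-decoded slices may contain negative values (the decoder is a
    signed filter); they are kept as-is.
    """

    z_mm: float
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"slice must be square, got {self.pixels.shape}")

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ImageStack:
    """Ordered reconstructions of one detector image at increasing depths."""

    slices: list[ReconSlice]
    method: str
    resized: bool = False
    failures: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = self.z_values
        if len(z) > 1 and np.any(np.diff(z) <= 0):
            raise ValueError("slice distances must be strictly increasing")

    @property
    def z_values(self) -> np.ndarray:
        return np.array([s.z_mm for s in self.slices])

    @property
    def step_mm(self) -> float:
        z = self.z_values
        if len(z) < 2:
            raise ValueError("step undefined for stacks with < 2 slices")
        steps = np.diff(z)
        if not np.allclose(steps, steps[0]):
            raise ValueError("stack is not on a uniform z grid")
        return float(steps[0])

    def __len__(self) -> int:
        return len(self.slices)

    def __getitem__(self, i: int) -> ReconSlice:
        return self.slices[i]

    def nearest_index(self, z_mm: float) -> int:
        return int(np.argmin(np.abs(self.z_values - z_mm)))

    def as_array(self) -> np.ndarray:
        """(n_slices, side, side) array; requires a uniform slice size."""
        sides = {s.side_px for s in self.slices}
        if len(sides) != 1:
            raise ValueError(
                f"slices have mixed sizes {sorted(sides)}; resize the stack first"
            )
        return np.stack([s.pixels for s in self.slices])
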