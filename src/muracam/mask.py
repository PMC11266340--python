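"""MURA mask patterns and their decoding arrays.

A MURA (Modified Uniformly Redundant Array) of prime rank ``p`` is a
binary aperture pattern built from quadratic residues modulo ``p``.  Its
defining property is that the circular cross-correlation of the
(periodically tiled) pattern with its signed decoding array is a delta
function: a single peak on a perfectly flat pedestal.  That makes the
decoding array an exact inverse filter for the periodic shadow cast by
the 2x2 mask mosaic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sympy import isprime

__all__ = [
    "MaskPattern",
    "generate_mura_basic",
    "expand_ntht",
    "tile_mosaic",
    "decoding_array",
]


def generate_mura_basic(rank: int) -> np.ndarray:
    """Generate the rank x rank basic MURA pattern (1 = open cell).

    Cell (i, j) is open iff i != 0 and (j == 0 or the quadratic-residue
    characters of i and j modulo ``rank`` agree).  Row 0 is entirely
    closed and the pattern has exactly (rank^2 - 1) / 2 open cells.
    """
    if not isprime(rank):
        raise ValueError(
            f"MURA patterns exist only for prime rank; got {rank}"
        )
    residues = {(k * k) % rank for k in range(1, rank)}
    chi = np.array([0] + [1 if i in residues else -1 for i in range(1, rank)])
    a = np.zeros((rank, rank), dtype=np.int8)
    for i in range(1, rank):
        for j in range(rank):
            if j == 0:
                a[i, j] = 1
            else:
                a[i, j] = 1 if chi[i] * chi[j] == 1 else 0
    return a


def expand_ntht(basic: np.ndarray) -> np.ndarray:
    """Expand a pattern to its no-two-holes-touching (NTHT) form.

    Every cell is spread onto a doubled grid: cell (i, j) moves to
    (2i, 2j) and the interleaving cells stay closed, so no two open
    cells are adjacent.  The open-cell count is preserved.
    """
    basic = np.asarray(basic)
    out = np.zeros((2 * basic.shape[0], 2 * basic.shape[1]), dtype=basic.dtype)
    out[::2, ::2] = basic
    return out


def tile_mosaic(pattern: np.ndarray) -> np.ndarray:
    """Duplicate a square pattern in a 2x2 arrangement (plain tiling)."""
    pattern = np.asarray(pattern)
    if pattern.ndim != 2 or pattern.shape[0] != pattern.shape[1]:
        raise ValueError(f"expected a square pattern, got shape {pattern.shape}")
    return np.tile(pattern, (2, 2))


def decoding_array(basic: np.ndarray) -> np.ndarray:
    """Signed decoding array for a basic MURA pattern.

    +1 where the pattern is open, -1 where closed, with the (0, 0)
    element forced to +1.  Circular cross-correlation of the tiled
    pattern with this array is a delta function (flat sidelobes).
    """
    basic = np.asarray(basic)
    g = np.where(basic == 1, 1, -1).astype(np.int8)
    g[0, 0] = 1
    return g


@dataclass(frozen=True)
class MaskPattern:
    """Binary open/closed cell arrays of the physical mask and its decoder.

    ``basic`` is the rank x rank MURA; ``ntht`` the doubled-grid
    no-two-holes-touching variant manufactured in the Tungsten sheet;
    ``mosaic`` the 2x2 tiling of ``ntht`` (the full physical mask);
    ``decoding`` the signed inverse filter matching ``basic``.
    """

    rank: int
    basic: np.ndarray
    ntht: np.ndarray
    mosaic: np.ndarray
    decoding: np.ndarray

    @classmethod
    def from_rank(cls, rank: int) -> "MaskPattern":
        basic = generate_mura_basic(rank)
        ntht = expand_ntht(basic)
        return cls(
            rank=rank,
            basic=basic,
            ntht=ntht,
            mosaic=tile_mosaic(ntht),
            decoding=decoding_array(basic),
        )

    @property
    def open_cells(self) -> int:
        return int(self.basic.sum())
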