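"""Padded-FFT linear convolution/correlation with cached kernel transforms.

The MLEM forward and backward projectors must be exact adjoints of each
other; both are implemented here from one cached kernel FFT on a
zero-padded grid, which also avoids the unintended circular wrap-around
a naive FFT product would introduce.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft

__all__ = ["LinearConvolver"]


class LinearConvolver:
    """'same'-aligned linear convolution and its adjoint on a fixed N x N grid.

    ``conv(x)`` equals ``scipy.signal.fftconvolve(x, kernel, mode='same')``;
    ``corr(y)`` is the exact adjoint operator (back-projection).
    """

    def __init__(self, kernel: np.ndarray):
        kernel = np.asarray(kernel, dtype=float)
        if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
            raise ValueError(f"expected a square 2D kernel, got {kernel.shape}")
        self.n = kernel.shape[0]
        self.size = sp_fft.next_fast_len(2 * self.n - 1)
        self.offset = (self.n - 1) // 2
        self._hhat = sp_fft.rfft2(kernel, s=(self.size, self.size))
        self.kernel_sum = float(kernel.sum())

    def conv(self, x: np.ndarray) -> np.ndarray:
        """Linear convolution with the kernel, 'same' alignment."""
        s = (self.size, self.size)
        y = sp_fft.irfft2(sp_fft.rfft2(x, s=s) * self._hhat, s=s)
        a, n = self.offset, self.n
        return y[a:a + n, a:a + n]

    def corr(self, y: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`conv` (cross-correlation back-projection)."""
        s = (self.size, self.size)
        a, n = self.offset, self.n
        ypad = np.zeros(s)
        ypad[a:a + n, a:a + n] = y
        w = sp_fft.irfft2(sp_fft.rfft2(ypad) * np.conj(self._hhat), s=s)
        return w[:n, :n]
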