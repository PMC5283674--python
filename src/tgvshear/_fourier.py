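"""Fourier-domain helpers shared by the TGV operators and the ADMM solver.

All difference operators in this package use periodic (circular) boundary
conditions, so every linear sub-step is diagonal (or block-diagonal) in the
discrete Fourier basis.  Real FFTs are used throughout: every filter and
difference symbol appearing here is even under frequency negation, so the
half-plane rfft grid carries the full information for real images.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft


def rfft2(a: np.ndarray) -> np.ndarray:
    return _fft.rfft2(a)


def irfft2(A: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return _fft.irfft2(A, s=shape)


def diff_symbols(shape: tuple[int, int]):
    """Fourier symbols of the periodic forward-difference operators.

    Returns (d1, d2) on the rfft grid, where d_k is the symbol of the
    forward difference along axis k.  The backward difference has symbol
    -conj(d_k), consistent with (forward)^* = -backward.
    """
    m1, m2 = shape
    w1 = 2.0 * np.pi * _fft.fftfreq(m1)
    w2 = 2.0 * np.pi * _fft.rfftfreq(m2)
    d1 = (np.exp(1j * w1) - 1.0)[:, None] * np.ones(w2.size)[None, :]
    d2 = np.ones(m1)[:, None] * (np.exp(1j * w2) - 1.0)[None, :]
    return d1, d2


def solve_vector_field(c1: float, c2: float, a1, a2, b11, b12, b22,
                       shape: tuple[int, int]):
    """Solve the coupled linear system for a per-pixel 2-vector field p:

        (c1 I + c2 E*E) p = c1 a + c2 E* b

    where E is the symmetrized gradient (backward differences, off-diagonal
    averaged) and E* its adjoint under the Frobenius pairing that counts the
    off-diagonal plane twice.  a = (a1, a2) anchors p directly; b = (b11,
    b12, b22) anchors E p.  Diagonalizes into independent 2x2 Hermitian
    systems per frequency.
    """
    d1f, d2f = diff_symbols(shape)
    # backward-difference symbols
    e1 = -np.conj(d1f)
    e2 = -np.conj(d2f)
    q1 = np.abs(e1) ** 2
    q2 = np.abs(e2) ** 2

    A11 = c1 + c2 * (q1 + 0.5 * q2)
    A22 = c1 + c2 * (q2 + 0.5 * q1)
    A12 = c2 * 0.5 * np.conj(e2) * e1

    B11 = rfft2(b11)
    B12 = rfft2(b12)
    B22 = rfft2(b22)
    r1 = c1 * rfft2(a1) + c2 * (np.conj(e1) * B11 + np.conj(e2) * B12)
    r2 = c1 * rfft2(a2) + c2 * (np.conj(e1) * B12 + np.conj(e2) * B22)

    det = A11 * A22 - np.abs(A12) ** 2
    p1 = (A22 * r1 - A12 * r2) / det
    p2 = (A11 * r2 - np.conj(A12) * r1) / det
    return irfft2(p1, shape), irfft2(p2, shape)
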