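"""Discrete difference operators and second-order total generalized variation.

The second-order TGV semi-norm of an image u with weights (gamma0, gamma1) is

    TGV2(u) = min_v  gamma1 ||grad(u) - v||_1 + gamma0 ||sym_grad(v)||_1

where v ranges over per-pixel 2-vector fields, ||.||_1 on a vector field sums
the per-pixel Euclidean norms, and on a symmetric tensor field it sums
per-pixel Frobenius norms (the off-diagonal plane counted twice).  TGV2
vanishes exactly on affine images, which is what suppresses the staircase
artifact of plain total variation.

All differences are periodic so that, together with the FFT-based
convolutions in :mod:`tgvshear.degrade`, every linear operator in the solver
is diagonal in Fourier space and the adjoint identities
(div1)* = -grad and (div2)* = -sym_grad hold exactly.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from . import _fourier


class VectorField(NamedTuple):
    """Per-pixel 2-vector field (v1, v2), each an m1 x m2 array."""

    v1: np.ndarray
    v2: np.ndarray


class SymTensorField(NamedTuple):
    """Per-pixel symmetric 2x2 tensor field; w21 == w12 is implicit."""

    w11: np.ndarray
    w12: np.ndarray
    w22: np.ndarray


def _dxp(u):  # forward difference, axis 0, periodic
    return np.roll(u, -1, axis=0) - u


def _dyp(u):
    return np.roll(u, -1, axis=1) - u


def _dxm(u):  # backward difference, axis 0, periodic
    return u - np.roll(u, 1, axis=0)


def _dym(u):
    return u - np.roll(u, 1, axis=1)


def grad(u: np.ndarray) -> VectorField:
    """Forward-difference gradient mapping images to vector fields."""
    u = np.asarray(u, dtype=float)
    return VectorField(_dxp(u), _dyp(u))


def sym_grad(v: VectorField) -> SymTensorField:
    """Symmetrized backward-difference gradient of a vector field."""
    v1, v2 = v
    return SymTensorField(_dxm(v1), 0.5 * (_dym(v1) + _dxm(v2)), _dym(v2))


def div1(v: VectorField) -> np.ndarray:
    """Backward-difference divergence; satisfies (div1)* = -grad."""
    v1, v2 = v
    return _dxm(v1) + _dym(v2)


def div2(w: SymTensorField) -> VectorField:
    """Forward-difference tensor divergence; satisfies (div2)* = -sym_grad."""
    w11, w12, w22 = w
    return VectorField(_dxp(w11) + _dyp(w12), _dxp(w12) + _dyp(w22))


def norm1_vec(v: VectorField) -> float:
    """Sum over pixels of the Euclidean norm of the 2-vector."""
    v1, v2 = v
    return float(np.sum(np.hypot(v1, v2)))


def norm1_sym(w: SymTensorField) -> float:
    """Sum over pixels of the Frobenius norm, off-diagonal counted twice."""
    w11, w12, w22 = w
    return float(np.sum(np.sqrt(w11 ** 2 + 2.0 * w12 ** 2 + w22 ** 2)))


def shrink2(a1: np.ndarray, a2: np.ndarray, mu: float):
    """Vectorial soft threshold: prox of mu * (per-pixel Euclidean norm)."""
    mag = np.hypot(a1, a2)
    scale = np.zeros_like(mag)
    nz = mag > 0
    scale[nz] = np.maximum(mag[nz] - mu, 0.0) / mag[nz]
    return a1 * scale, a2 * scale


def shrinkF(w11, w12, w22, mu: float):
    """Frobenius soft threshold on symmetric 2x2 tensors (w12 counted twice)."""
    mag = np.sqrt(w11 ** 2 + 2.0 * w12 ** 2 + w22 ** 2)
    scale = np.zeros_like(mag)
    nz = mag > 0
    scale[nz] = np.maximum(mag[nz] - mu, 0.0) / mag[nz]
    return w11 * scale, w12 * scale, w22 * scale


def tgv2_value(u: np.ndarray, gamma0: float = 2.0, gamma1: float = 1.0,
               n_iter: int = 100) -> float:
    """Approximate TGV2 value of an image by a small internal ADMM loop.

    Diagnostic only; the restoration solver carries the auxiliary field
    explicitly.  The inner minimization over v uses splitting variables
    y = grad(u) - v and z = sym_grad(v) with closed-form shrinkage updates
    and a Fourier-diagonal solve for v.

    Because the differences are periodic, a global linear trend in u would
    create a spurious wrap-around seam; the minimization therefore also
    ranges over a global linear trend (two extra unknowns), which restores
    the defining property that the semi-norm vanishes on affine images
    while leaving the value on trend-free images untouched (trend zero is
    always feasible, so the gamma1 * ||grad(u)||_1 feasibility bound still
    holds).
    """
    if gamma0 <= 0 or gamma1 <= 0:
        raise ValueError("TGV weights must be strictly positive")
    u = np.asarray(u, dtype=float)
    shape = u.shape
    gu1, gu2 = grad(u)
    # periodic gradients of the two linear-trend basis images
    ii = np.arange(shape[0], dtype=float)[:, None] * np.ones(shape[1])
    jj = np.ones(shape[0])[:, None] * np.arange(shape[1], dtype=float)
    B1 = grad(ii)   # (v1, v2) of the row ramp
    B2 = grad(jj)
    ta = tb = 0.0   # trend coefficients
    g1, g2 = gu1.copy(), gu2.copy()
    rho = 1.0
    v1 = np.zeros(shape)
    v2 = np.zeros(shape)
    y1 = np.zeros(shape)
    y2 = np.zeros(shape)
    z11 = np.zeros(shape)
    z12 = np.zeros(shape)
    z22 = np.zeros(shape)
    yt1 = np.zeros(shape)
    yt2 = np.zeros(shape)
    zt11 = np.zeros(shape)
    zt12 = np.zeros(shape)
    zt22 = np.zeros(shape)
    for _ in range(n_iter):
        y1, y2 = shrink2(g1 - v1 + yt1, g2 - v2 + yt2, gamma1 / rho)
        e11, e12, e22 = sym_grad(VectorField(v1, v2))
        z11, z12, z22 = shrinkF(e11 + zt11, e12 + zt12, e22 + zt22,
                                gamma0 / rho)
        v1, v2 = _fourier.solve_vector_field(
            rho, rho,
            g1 - y1 + yt1, g2 - y2 + yt2,
            z11 - zt11, z12 - zt12, z22 - zt22, shape)
        # trend update: least squares fit of (grad(u) - trend) to v + y - yt
        r1 = gu1 - v1 - y1 + yt1
        r2 = gu2 - v2 - y2 + yt2
        a11 = np.sum(B1.v1 ** 2 + B1.v2 ** 2)
        a22 = np.sum(B2.v1 ** 2 + B2.v2 ** 2)
        a12 = np.sum(B1.v1 * B2.v1 + B1.v2 * B2.v2)
        c1 = np.sum(B1.v1 * r1 + B1.v2 * r2)
        c2 = np.sum(B2.v1 * r1 + B2.v2 * r2)
        det = a11 * a22 - a12 ** 2
        if det > 0:
            ta = (a22 * c1 - a12 * c2) / det
            tb = (a11 * c2 - a12 * c1) / det
        g1 = gu1 - ta * B1.v1 - tb * B2.v1
        g2 = gu2 - ta * B1.v2 - tb * B2.v2
        e11, e12, e22 = sym_grad(VectorField(v1, v2))
        yt1 += g1 - v1 - y1
        yt2 += g2 - v2 - y2
        zt11 += e11 - z11
        zt12 += e12 - z12
        zt22 += e22 - z22
    e = sym_grad(VectorField(v1, v2))
    return (gamma1 * norm1_vec(VectorField(g1 - v1, g2 - v2))
            + gamma0 * norm1_sym(e))
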