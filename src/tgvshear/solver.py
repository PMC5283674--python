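"""ADMM restoration of images degraded by blur and multiplicative noise.

The model restores u from  f = (H u) . eta  (eta mean-one Gamma speckle,
H a known convolution) by minimizing

    E(u, p) = <log(Hu), 1> + <f/Hu, 1> + alpha ||Hu/f - 1||_2^2
              + lambda sum_j ||SH_j(u)||_1
              + gamma1 ||grad(u) - p||_1 + gamma0 ||sym_grad(p)||_1

i.e. the Gamma maximum-a-posteriori fidelity plus a quadratic ratio term
(alpha >= 26/9 for coercivity), shearlet-coefficient sparsity, and
second-order total generalized variation carried by the auxiliary vector
field p.  The ADMM splitting introduces x_j = SH_j(u), y = grad(u) - p,
z = sym_grad(p); the x/y/z updates are closed-form shrinkages, and the
(u, p) subproblem alternates a Fourier-diagonal linear solve for p with a
u-update that separates the pointwise fidelity nonlinearity in t = Hu
(damped Newton with a positivity safeguard) from the convolutional
coupling (another Fourier-diagonal solve).

Intensities are normalized to [0, 1] internally: the log/ratio fidelity is
not scale-invariant and the stated weight ranges (lambda in [1.5, 10])
balance it against the regularizers at unit scale.  Inputs and outputs
remain on the [0, N_max] gray-level scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft

from . import _fourier, shearlet
from .degrade import (CrossChannelBlur, ImageGrid, Psf, as_pixels,
                      cross_channel_otf, psf_otf)

#: coercivity bound on the quadratic-fidelity weight
ALPHA_MIN = 26.0 / 9.0


class SolverDivergence(RuntimeError):
    """Raised when the energy rises for many consecutive iterations."""

    def __init__(self, message, history):
        super().__init__(message)
        self.history = history


@dataclass
class InnerConfig:
    """Settings of the (u, p) inner solver."""

    sweeps: int = 1          # p/u alternations per outer iteration
    t_steps: int = 2         # splitting iterations on t = Hu
    newton_iters: int = 8    # damped-Newton iterations per t update
    rho: float = 50.0        # penalty coupling t = Hu (unit-scale intensities)
    eps_pos: float = 1e-3    # positivity floor on the unit intensity scale


@dataclass
class SolverConfig:
    lam: float = 5.0         # shearlet-sparsity weight (paper range [1.5, 10])
    alpha: float = 3.0       # quadratic-fidelity weight, >= 26/9
    gamma0: float = 2.0      # second-order TGV weight
    gamma1: float = 1.0      # first-order TGV weight
    mu1: float = 10.0        # quadratic penalty, shearlet constraint
    mu2: float = 10.0        # quadratic penalty, gradient constraint
    mu3: float = 10.0        # quadratic penalty, symmetrized-gradient constraint
    mu: float = 1.0          # dual-ascent step
    beta: float | None = None  # legacy alias for mu (augmented-penalty role)
    max_iter: int = 400
    tol: float = 2e-5        # relative-change stopping threshold
    n_scales: int = 4
    # the ADMM iterates shearlet auxiliaries for the directional bands only
    # (an l1 penalty on the scaling band systematically darkens the image);
    # set True to penalize the j=0 band as well
    penalize_lowpass: bool = False
    inner: InnerConfig = field(default_factory=InnerConfig)
    N_max: float = 255.0
    seed: int = 0

    def __post_init__(self):
        if self.beta is not None:
            self.mu = self.beta
        for name in ("mu1", "mu2", "mu3", "mu", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("lam", "alpha", "gamma0", "gamma1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.alpha < ALPHA_MIN:
            warnings.warn(
                f"alpha={self.alpha:g} is below the coercivity bound "
                f"26/9 ~= {ALPHA_MIN:.4f}; the energy may lose its unique "
                "minimizer", stacklevel=2)


@dataclass
class ADMMState:
    """All primal and scaled dual variables of the splitting."""

    u: np.ndarray            # (m, m1, m2)
    p: np.ndarray            # (m, 2, m1, m2)
    x: np.ndarray            # (m, n_pen, m1, m2) shearlet auxiliaries
    y: np.ndarray            # (m, 2, m1, m2)
    z: np.ndarray            # (m, 3, m1, m2)
    xd: np.ndarray           # scaled duals, same shapes as x / y / z
    yd: np.ndarray
    zd: np.ndarray
    t: np.ndarray            # (m, m1, m2) inner auxiliary t = Hu
    s: np.ndarray            # (m, m1, m2) inner scaled dual for t
    iter: int = 0
    history: dict = field(default_factory=lambda: {
        "energy": [], "rel_change": [],
        "res_shear": [], "res_grad": [], "res_sym": []})


# ---------------------------------------------------------------------------
# shrinkage operators

def shrink1(v: np.ndarray, sigma: float) -> np.ndarray:
    """Elementwise soft threshold sgn(v) max(|v| - sigma, 0)."""
    if sigma < 0:
        raise ValueError("threshold must be nonnegative")
    return np.sign(v) * np.maximum(np.abs(v) - sigma, 0.0)


def shrink2(a: np.ndarray, mu: float) -> np.ndarray:
    """Per-pixel vectorial soft threshold; ``a`` has the 2-vector on axis 0.

    Magnitudes at or below mu are clamped to zero (prox of the l2 norm).
    """
    mag = np.sqrt(np.sum(a ** 2, axis=0))
    scale = np.zeros_like(mag)
    nz = mag > 0
    scale[nz] = np.maximum(mag[nz] - mu, 0.0) / mag[nz]
    return a * scale


def shrinkF(w: np.ndarray, mu: float) -> np.ndarray:
    """Frobenius soft threshold; ``w`` stacks (w11, w12, w22) on axis 0,
    the off-diagonal plane counted twice in the norm."""
    mag = np.sqrt(w[0] ** 2 + 2.0 * w[1] ** 2 + w[2] ** 2)
    scale = np.zeros_like(mag)
    nz = mag > 0
    scale[nz] = np.maximum(mag[nz] - mu, 0.0) / mag[nz]
    return w * scale


# ---------------------------------------------------------------------------
# stacked difference operators (channel-first layout)

def _grad(u):
    return np.stack([np.roll(u, -1, axis=-2) - u,
                     np.roll(u, -1, axis=-1) - u], axis=-3)


def _sym_grad(p):
    p1, p2 = p[..., 0, :, :], p[..., 1, :, :]
    dxm = lambda a: a - np.roll(a, 1, axis=-2)
    dym = lambda a: a - np.roll(a, 1, axis=-1)
    return np.stack([dxm(p1), 0.5 * (dym(p1) + dxm(p2)), dym(p2)], axis=-3)


def _vec_norm1(v):
    return float(np.sum(np.sqrt(np.sum(v ** 2, axis=-3))))


def _sym_norm1(w):
    return float(np.sum(np.sqrt(w[..., 0, :, :] ** 2
                                + 2.0 * w[..., 1, :, :] ** 2
                                + w[..., 2, :, :] ** 2)))


# ---------------------------------------------------------------------------
# problem context

class _Problem:
    """Precomputed operators for a fixed image shape / blur / config."""

    def __init__(self, f_unit: np.ndarray, Hhat, cfg: SolverConfig):
        self.f = f_unit                      # (m, m1, m2), unit scale
        self.m = f_unit.shape[0]
        self.shape = f_unit.shape[1:]
        self.cfg = cfg
        self.Hhat = Hhat                     # (m, m, F1, F2) complex or None
        if cfg.lam > 0:
            self.sys = shearlet.cached_system(self.shape[0], self.shape[1],
                                              cfg.n_scales)
        else:
            # sparsity term disabled: a single all-pass band keeps the
            # machinery trivial (and supports arbitrarily small images)
            self.sys = shearlet.ShearletSystem(
                filters=np.ones((1,) + self.shape), n_scales=0,
                shape=self.shape)
        self.j0 = 0 if (cfg.penalize_lowpass and cfg.lam > 0) else 1
        self.n_pen = self.sys.n_bands - self.j0
        fh = self.sys.filters_half
        self.G = np.sum(fh[self.j0:] ** 2, axis=0)   # rfft-grid symbol

        d1, d2 = _fourier.diff_symbols(self.shape)
        self.d1, self.d2 = d1, d2
        self.DtD = np.abs(d1) ** 2 + np.abs(d2) ** 2

        c = cfg.lam * cfg.mu1 * self.G + cfg.gamma1 * cfg.mu2 * self.DtD
        rho = cfg.inner.rho
        if Hhat is None:
            self.uinv = 1.0 / (c + rho)
        elif self.m == 1:
            self.uinv = 1.0 / (c + rho * np.abs(Hhat[0, 0]) ** 2)
        else:
            m = self.m
            HtH = np.einsum("kl...,kn...->ln...", np.conj(Hhat), Hhat)
            A = np.moveaxis(HtH, (0, 1), (-2, -1)) * rho
            A = A + c[..., None, None] * np.eye(m)
            self.uinv = np.linalg.inv(A)     # (F1, F2, m, m)

        # rfft quadrature weights for <u, G u> evaluated on the half grid
        m2 = self.shape[1]
        w = np.full(m2 // 2 + 1, 2.0)
        w[0] = 1.0
        if m2 % 2 == 0:
            w[-1] = 1.0
        self.rweight = w

    # -- linear operators ---------------------------------------------------
    def apply_H(self, u):
        if self.Hhat is None:
            return u.copy()
        out = np.empty_like(u)
        for k in range(self.m):
            acc = np.zeros(self.Hhat.shape[2:], dtype=complex)
            for l in range(self.m):
                acc += self.Hhat[k, l] * _fourier.rfft2(u[l])
            out[k] = _fourier.irfft2(acc, self.shape)
        return out

    def forward_shear(self, u):
        """All shearlet bands per channel: (m, n_bands, m1, m2)."""
        U = _fft.rfft2(u, axes=(-2, -1))
        return _fft.irfft2(U[:, None] * self.sys.filters_half[None],
                           s=self.shape, axes=(-2, -1))

    def adjoint_pen(self, c):
        """Adjoint over the penalized bands; c is (m, n_pen, m1, m2)."""
        Ch = _fft.rfft2(c, axes=(-2, -1))
        acc = np.sum(self.sys.filters_half[None, self.j0:] * Ch, axis=1)
        return _fft.irfft2(acc, s=self.shape, axes=(-2, -1))

    def quad_shear(self, u, C):
        """<u, G u> - 2 <u, C> for the collapsed shearlet quadratic."""
        tot = 0.0
        n = self.shape[0] * self.shape[1]
        for k in range(self.m):
            U = _fourier.rfft2(u[k])
            tot += np.sum(self.rweight * self.G * np.abs(U) ** 2) / n
        return tot - 2.0 * float(np.sum(u * C))

    # -- fidelity -----------------------------------------------------------
    def fid(self, t):
        t = np.maximum(t, 1e-12)
        r = t / self.f
        return float(np.sum(np.log(t) + self.f / t
                            + self.cfg.alpha * (r - 1.0) ** 2))

    def newton_t(self, t0, anchor):
        """argmin_t  log t + f/t + alpha (t/f - 1)^2 + rho/2 (t - anchor)^2,
        solved per pixel by damped Newton with a positivity safeguard.
        The objective is strictly convex on t > 0 for any alpha > 1/54."""
        cfg = self.cfg
        rho = cfg.inner.rho
        f = self.f
        tmin = 1e-8
        t = np.maximum(t0, tmin)
        for _ in range(cfg.inner.newton_iters):
            g = (1.0 / t - f / t ** 2
                 + 2.0 * cfg.alpha * (t / f - 1.0) / f + rho * (t - anchor))
            h = (-1.0 / t ** 2 + 2.0 * f / t ** 3
                 + 2.0 * cfg.alpha / f ** 2 + rho)
            step = g / h
            tn = t - step
            bad = tn <= tmin
            tn[bad] = 0.5 * (t[bad] + tmin)
            t = tn
        return np.maximum(t, tmin)


class _UPSolver:
    """Inner solver for the joint (u, p) subproblem.

    The p update is the exact minimizer (Fourier-diagonal 2x2 solve); the u
    update is an inexact splitting step on t = Hu whose scaled dual ``s``
    persists across outer iterations, the standard warm-started inexact-ADMM
    arrangement.  Individual u steps need not decrease the subproblem
    objective; sustained growth is caught by the outer divergence detector.
    """

    def __init__(self, prob: _Problem):
        self.prob = prob

    def objective(self, u, p, C, y_anchor, z_anchor, Hu):
        """Subproblem objective up to an additive constant (diagnostic)."""
        prob, cfg = self.prob, self.prob.cfg
        val = cfg.lam * cfg.mu1 / 2.0 * prob.quad_shear(u, C)
        val += cfg.gamma1 * cfg.mu2 / 2.0 * float(
            np.sum((_grad(u) - p - y_anchor) ** 2))
        val += cfg.gamma0 * cfg.mu3 / 2.0 * float(
            np.sum((_sym_grad(p) - z_anchor) ** 2))
        val += prob.fid(np.maximum(Hu, 1e-12))
        return val

    def solve(self, state: ADMMState):
        prob, cfg = self.prob, self.prob.cfg
        inner = cfg.inner
        u, p, t, s = state.u, state.p, state.t, state.s
        c_bands = state.x - state.xd                  # anchors for SH_j(u)
        C = prob.adjoint_pen(c_bands)
        y_anchor = state.y - state.yd                 # anchor for grad(u) - p
        z_anchor = state.z - state.zd                 # anchor for sym_grad(p)
        Chat = np.stack([_fourier.rfft2(C[k]) for k in range(prob.m)])

        Hu = prob.apply_H(u)
        for _ in range(inner.sweeps):
            # p given u: (g1*mu2) (p - (grad u - y_anchor)) solved jointly
            # with the (g0*mu3) sym-grad coupling, per channel in Fourier
            gu = _grad(u)
            for k in range(prob.m):
                a = gu[k] - y_anchor[k]
                b = z_anchor[k]
                p1, p2 = _fourier.solve_vector_field(
                    cfg.gamma1 * cfg.mu2, cfg.gamma0 * cfg.mu3,
                    a[0], a[1], b[0], b[1], b[2], prob.shape)
                p[k, 0], p[k, 1] = p1, p2

            # u given p: split t = Hu; pointwise Newton in t, then a
            # Fourier-diagonal (or per-frequency block) solve in u
            g = p + y_anchor
            rhs0 = np.empty((prob.m,) + Chat.shape[1:], dtype=complex)
            for k in range(prob.m):
                G1 = _fourier.rfft2(g[k, 0])
                G2 = _fourier.rfft2(g[k, 1])
                rhs0[k] = (cfg.lam * cfg.mu1 * Chat[k]
                           + cfg.gamma1 * cfg.mu2
                           * (np.conj(prob.d1) * G1 + np.conj(prob.d2) * G2))
            for _ in range(inner.t_steps):
                t = prob.newton_t(t, Hu + s)
                ts = t - s
                TS = np.stack([_fourier.rfft2(ts[k]) for k in range(prob.m)])
                if prob.Hhat is None:
                    rhs = rhs0 + inner.rho * TS
                    U = rhs * prob.uinv
                elif prob.m == 1:
                    rhs = rhs0 + inner.rho * np.conj(prob.Hhat[0, 0]) * TS
                    U = rhs * prob.uinv
                else:
                    rhs = rhs0 + inner.rho * np.einsum(
                        "kl...,k...->l...", np.conj(prob.Hhat), TS)
                    U = np.einsum("...lk,k...->l...",
                                  prob.uinv, rhs)
                u = np.stack([_fourier.irfft2(U[k], prob.shape)
                              for k in range(prob.m)])
                Hu = prob.apply_H(u)
                s = s + Hu - t

        state.u, state.p, state.t, state.s = u, p, t, s
        return u, p


# ---------------------------------------------------------------------------
# energy

def _as_otf(H, shape, m):
    if H is None:
        return None
    if isinstance(H, Psf):
        base = psf_otf(H, shape)
        out = np.zeros((m, m) + base.shape, dtype=complex)
        for k in range(m):
            out[k, k] = base
        return out
    if isinstance(H, CrossChannelBlur):
        return cross_channel_otf(H, shape)
    raise TypeError("H must be a Psf, CrossChannelBlur or None")


def energy(u, p, f, H=None, cfg: SolverConfig | None = None) -> float:
    """Objective value E(u, p) of the restoration model (quadratic ratio
    fidelity).  ``u`` and ``f`` must be strictly positive and on the same
    intensity scale; ``p`` is a VectorField-style pair or a (2, m1, m2)
    array (or stacked per channel)."""
    if cfg is None:
        cfg = SolverConfig()
    up = as_pixels(u)
    fp = as_pixels(f)
    if up.ndim == 2:
        up = up[None]
        fp = fp[None]
    parr = np.asarray(p, dtype=float)
    if parr.ndim == 3:
        parr = parr[None]
    if np.any(fp <= 0):
        raise ValueError("f must be strictly positive")
    Hhat = _as_otf(H, up.shape[1:], up.shape[0])
    prob = _Problem(fp, Hhat, cfg)
    Hu = prob.apply_H(up)
    if np.any(Hu <= 0):
        raise ValueError("Hu must be strictly positive")
    val = prob.fid(Hu)
    if cfg.lam > 0:
        bands = prob.forward_shear(up)
        val += cfg.lam * float(np.sum(np.abs(bands[:, prob.j0:])))
    val += cfg.gamma1 * _vec_norm1(_grad(up) - parr)
    val += cfg.gamma0 * _sym_norm1(_sym_grad(parr))
    return val


# ---------------------------------------------------------------------------
# main loop

def _init_state(prob: _Problem) -> ADMMState:
    m, (m1, m2) = prob.m, prob.shape
    u = prob.f.copy()
    Hu = prob.apply_H(u)
    return ADMMState(
        u=u,
        p=np.zeros((m, 2, m1, m2)),
        x=np.zeros((m, prob.n_pen, m1, m2)),
        y=np.zeros((m, 2, m1, m2)),
        z=np.zeros((m, 3, m1, m2)),
        xd=np.zeros((m, prob.n_pen, m1, m2)),
        yd=np.zeros((m, 2, m1, m2)),
        zd=np.zeros((m, 3, m1, m2)),
        t=np.maximum(Hu, prob.cfg.inner.eps_pos),
        s=np.zeros((m, m1, m2)),
    )


def solve_up_subproblem(state: ADMMState, f, H, cfg: SolverConfig):
    """One pass of the joint (u, p) inner solver on an explicit state.

    ``f`` is on the unit intensity scale with the same stacked layout as
    ``state.u``.  Returns the updated (u, p).
    """
    fp = as_pixels(f)
    if fp.ndim == 2:
        fp = fp[None]
    Hhat = _as_otf(H, fp.shape[1:], fp.shape[0])
    prob = _Problem(fp, Hhat, cfg)
    return _UPSolver(prob).solve(state)


def _restore_core(f_gray: np.ndarray, Hhat, cfg: SolverConfig):
    """Run the ADMM on a (m, m1, m2) gray-level stack; returns (u, diag)."""
    eps = cfg.inner.eps_pos
    f = np.maximum(f_gray / cfg.N_max, eps)
    prob = _Problem(f, Hhat, cfg)
    state = _init_state(prob)
    upsolver = _UPSolver(prob)

    Su = prob.forward_shear(state.u)
    rise = 0
    energy_prev = np.inf
    converged = False
    for it in range(1, cfg.max_iter + 1):
        gu = _grad(state.u)
        ep = _sym_grad(state.p)
        state.x = shrink1(Su[:, prob.j0:] + state.xd, 1.0 / cfg.mu1)
        for k in range(prob.m):
            state.y[k] = shrink2(gu[k] - state.p[k] + state.yd[k],
                                 1.0 / cfg.mu2)
            state.z[k] = shrinkF(ep[k] + state.zd[k], 1.0 / cfg.mu3)

        u_prev = state.u.copy()
        upsolver.solve(state)

        Su = prob.forward_shear(state.u)
        gu = _grad(state.u)
        ep = _sym_grad(state.p)
        r_shear = Su[:, prob.j0:] - state.x
        r_grad = gu - state.p - state.y
        r_sym = ep - state.z
        state.xd += cfg.mu * r_shear
        state.yd += cfg.mu * r_grad
        state.zd += cfg.mu * r_sym

        rel = (np.linalg.norm(state.u - u_prev)
               / max(np.linalg.norm(u_prev), 1e-30))
        Hu = prob.apply_H(state.u)
        e_val = prob.fid(np.maximum(Hu, 1e-12))
        e_val += cfg.lam * float(np.sum(np.abs(Su[:, prob.j0:])))
        e_val += cfg.gamma1 * _vec_norm1(gu - state.p)
        e_val += cfg.gamma0 * _sym_norm1(ep)

        h = state.history
        h["energy"].append(e_val)
        h["rel_change"].append(rel)
        h["res_shear"].append(float(np.linalg.norm(r_shear)))
        h["res_grad"].append(float(np.linalg.norm(r_grad)))
        h["res_sym"].append(float(np.linalg.norm(r_sym)))
        state.iter = it

        rise = rise + 1 if e_val > energy_prev else 0
        if rise >= 20:
            raise SolverDivergence(
                f"energy increased for {rise} consecutive iterations",
                state.history)
        energy_prev = e_val

        if rel <= cfg.tol:
            converged = True
            break

    u_out = np.clip(state.u * cfg.N_max, 0.0, cfg.N_max)
    diag = dict(state.history)
    diag["n_iter"] = state.iter
    diag["converged"] = converged
    return u_out, diag


def admm_restore(f, H: Psf | None = None, cfg: SolverConfig | None = None):
    """Restore a single-channel image; returns (u_hat, diagnostics).

    ``f`` is the degraded observation on the [0, N_max] gray scale, ``H``
    the known blur (None for pure denoising).  Diagnostics carry the
    per-iteration energy, relative change, and primal residual norms.
    """
    if cfg is None:
        cfg = SolverConfig()
    fp = as_pixels(f)
    if fp.ndim != 2:
        raise ValueError("admm_restore expects a single-channel image")
    Hhat = _as_otf(H, fp.shape, 1)
    u, diag = _restore_core(fp[None], Hhat, cfg)
    u = u[0]
    if isinstance(f, ImageGrid):
        return ImageGrid(u, N_max=f.N_max), diag
    return u, diag


def restore_multichannel(f, H: CrossChannelBlur | None = None,
                         cfg: SolverConfig | None = None):
    """Restore an m-channel image under a (possibly cross-channel) blur.

    The energy is summed over channels; the blur couples channels through
    (Hu)_k = sum_l w_kl K_kl * u_l while the regularizers act per channel.
    With m = 1 this reduces exactly to :func:`admm_restore`.
    """
    if cfg is None:
        cfg = SolverConfig()
    fp = as_pixels(f)
    if fp.ndim == 2:
        fp = fp[None]
    m = fp.shape[0]
    if H is not None and H.n_channels != m:
        raise ValueError("channel count mismatch between image and blur")
    Hhat = _as_otf(H, fp.shape[1:], m)
    u, diag = _restore_core(fp, Hhat, cfg)
    if m == 1:
        u = u[0]
    if isinstance(f, ImageGrid):
        return ImageGrid(u, N_max=f.N_max), diag
    return u, diag
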