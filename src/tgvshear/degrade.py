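"""Synthetic degradation: blur kernels, multiplicative noise, test images.

The degradation model is  f = (H u) . eta  with H a normalized convolution
(the point-spread function) and eta a mean-one multiplicative noise field —
Gamma with L looks (variance 1/L) for SAR-type speckle, Rayleigh for
ultrasound, or a clipped Gaussian.  Everything the test suite and the
acceptance scenarios consume is generated here, so the repository needs no
external imagery.

Blur kernels emulate the MATLAB ``fspecial`` families the literature
specifies experiments with (motion / gaussian / disk / average) plus a
Moffat profile; all kernels are nonnegative and normalized to unit sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from . import _fourier

#: positivity floor, as a fraction of the peak gray level, applied to every
#: image entering the log / ratio fidelity so log(Hu) and f/Hu stay finite.
EPS_POS = 1e-3


@dataclass
class ImageGrid:
    """Strictly-positive intensity field; gray levels nominally [0, N_max].

    ``pixels`` is (m1, m2) for grayscale or (n_channels, m1, m2) for
    multichannel images.
    """

    pixels: np.ndarray
    N_max: float = 255.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[-2:]


def as_pixels(img) -> np.ndarray:
    """Accept either an ImageGrid or a bare array; return the array."""
    if isinstance(img, ImageGrid):
        return img.pixels
    return np.asarray(img, dtype=float)


@dataclass
class BlurSpec:
    family: Literal["motion", "gaussian", "disk", "average", "moffat",
                    "identity"]
    params: dict = field(default_factory=dict)


@dataclass
class Psf:
    """Normalized 2-D convolution kernel realizing the blur operator H."""

    kernel: np.ndarray
    boundary: Literal["periodic", "symmetric"] = "periodic"

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float)
        if np.any(self.kernel < 0):
            raise ValueError("PSF weights must be nonnegative")
        s = self.kernel.sum()
        if abs(s - 1.0) > 1e-12:
            raise ValueError("PSF must sum to 1 (got %g)" % s)

    @property
    def anchor(self) -> tuple[int, int]:
        return (self.kernel.shape[0] // 2, self.kernel.shape[1] // 2)


@dataclass
class NoiseSpec:
    family: Literal["gamma", "rayleigh", "gaussian", "speckle_variance"]
    L: int | None = None
    sigma2: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.family in ("gamma",):
            if self.L is None or self.L < 1 or int(self.L) != self.L:
                raise ValueError("gamma noise requires integer L >= 1")
        if self.family in ("gaussian", "speckle_variance"):
            if self.sigma2 is None or self.sigma2 <= 0:
                raise ValueError("sigma2 must be > 0")


@dataclass
class CrossChannelBlur:
    """m x m grid of PSFs K_ij with a nonnegative weight matrix W.

    Channel k of the blurred image is sum_l w[k, l] * (K[k][l] * u_l); with
    W the identity the channels do not mix.
    """

    kernels: list  # m x m nested list of Psf
    weights: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


# ---------------------------------------------------------------------------
# PSF construction

def _motion_kernel(length: float, angle: float) -> np.ndarray:
    """Anti-aliased line segment of the given length and angle (degrees,
    counter-clockwise), matching fspecial('motion') semantics: length 1 is
    the identity, angle 90 transposes angle 0."""
    if length <= 0:
        raise ValueError("motion length must be positive")
    th = np.deg2rad(angle % 180.0)
    c, s = np.cos(th), np.sin(th)
    half = (length - 1) / 2.0
    # rows point down, so a counter-clockwise angle has direction
    # (d_row, d_col) = (-sin, cos); angle 0 is a horizontal line
    hr = int(np.ceil(abs(half * s) - 1e-9)) if half > 0 else 0
    hc = int(np.ceil(abs(half * c) - 1e-9)) if half > 0 else 0
    row = np.arange(-hr, hr + 1)[:, None]
    col = np.arange(-hc, hc + 1)[None, :]
    along = -row * s + col * c
    perp = np.abs(row * c + col * s)
    cover_along = np.clip(length / 2.0 - np.abs(along) + 0.5, 0.0, 1.0)
    cover_perp = np.clip(1.0 - perp, 0.0, 1.0)
    k = cover_along * cover_perp
    return k / k.sum()


def _gaussian_kernel(hsize: int, sigma: float) -> np.ndarray:
    if hsize <= 0 or sigma <= 0:
        raise ValueError("hsize and sigma must be positive")
    half = (hsize - 1) / 2.0
    x = np.arange(hsize) - half
    g = np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / (2.0 * sigma ** 2))
    return g / g.sum()


def _disk_kernel(radius: float, subsamples: int = 64) -> np.ndarray:
    """Pillbox of the given radius with fractional (area-weighted) edge
    pixels, approximated by subpixel sampling."""
    if radius <= 0:
        raise ValueError("disk radius must be positive")
    r = int(np.ceil(radius - 0.5))
    size = 2 * r + 1
    half = (subsamples - 1) / (2.0 * subsamples)
    sub = np.linspace(-half, half, subsamples)
    x = (np.arange(size) - r)[:, None, None, None] + sub[None, None, :, None]
    y = (np.arange(size) - r)[None, :, None, None] + sub[None, None, None, :]
    inside = (x ** 2 + y ** 2) <= radius ** 2
    k = inside.mean(axis=(2, 3))
    return k / k.sum()


def _moffat_kernel(hsize: int, s: float, beta: float) -> np.ndarray:
    """Moffat profile (1 + r^2/s^2)^(-beta) on an hsize x hsize window."""
    if hsize <= 0 or s <= 0 or beta <= 0:
        raise ValueError("hsize, s and beta must be positive")
    half = (hsize - 1) / 2.0
    x = np.arange(hsize) - half
    r2 = x[:, None] ** 2 + x[None, :] ** 2
    k = (1.0 + r2 / s ** 2) ** (-beta)
    return k / k.sum()


def make_psf(spec: BlurSpec) -> Psf:
    """Build a normalized PSF from a blur family specification."""
    p = spec.params
    if spec.family == "identity":
        k = np.ones((1, 1))
    elif spec.family == "motion":
        k = _motion_kernel(p.get("length", 9), p.get("angle", 0.0))
    elif spec.family == "gaussian":
        k = _gaussian_kernel(p.get("hsize", 3), p.get("sigma", 0.5))
    elif spec.family == "disk":
        k = _disk_kernel(p.get("radius", 5))
    elif spec.family == "average":
        h = p.get("hsize", 3)
        if h <= 0:
            raise ValueError("hsize must be positive")
        k = np.full((h, h), 1.0 / (h * h))
    elif spec.family == "moffat":
        k = _moffat_kernel(p.get("hsize", 7), p.get("s", 1.0),
                           p.get("beta", 5.0))
    else:
        raise ValueError(f"unknown blur family {spec.family!r}")
    k = k / k.sum()
    return Psf(kernel=k, boundary=p.get("boundary", "periodic"))


def psf_otf(psf: Psf, shape: tuple[int, int]) -> np.ndarray:
    """Transfer function of the PSF on the rfft grid of the given shape,
    with the kernel anchor placed at the origin (periodic embedding)."""
    m1, m2 = shape
    k = psf.kernel
    if k.shape[0] > m1 or k.shape[1] > m2:
        raise ValueError("kernel larger than image")
    big = np.zeros(shape)
    big[: k.shape[0], : k.shape[1]] = k
    ax, ay = psf.anchor
    big = np.roll(big, (-ax, -ay), axis=(0, 1))
    return _fourier.rfft2(big)


def apply_blur(u, psf: Psf):
    """Mean-preserving linear convolution of u with the PSF.

    Periodic boundaries go through the FFT (the convention the solver's
    Fourier-diagonal inner solves require); symmetric boundaries use
    reflective spatial convolution.  Multichannel images are blurred
    channel by channel.
    """
    pix = as_pixels(u)
    if pix.ndim == 3:
        out = np.stack([apply_blur(ch, psf) for ch in pix])
    elif psf.boundary == "periodic":
        otf = psf_otf(psf, pix.shape)
        out = _fourier.irfft2(otf * _fourier.rfft2(pix), pix.shape)
    else:
        if psf.kernel.shape[0] > pix.shape[0] or \
                psf.kernel.shape[1] > pix.shape[1]:
            raise ValueError("kernel larger than image")
        out = ndimage.convolve(pix, psf.kernel, mode="reflect")
    if isinstance(u, ImageGrid):
        return ImageGrid(out, N_max=u.N_max)
    return out


# ---------------------------------------------------------------------------
# Noise

def sample_noise(shape, spec: NoiseSpec) -> np.ndarray:
    """Sample a mean-one multiplicative noise field of the given shape.

    gamma: Gamma(shape=L, scale=1/L), variance 1/L.
    rayleigh: Rayleigh rescaled to unit mean (scale sqrt(2/pi)).
    gaussian: Normal(1, sigma2) clipped to strictly positive values.
    speckle_variance: Gamma with L = round(1/sigma2).
    Identical seeds produce identical fields.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.family == "gamma":
        return rng.gamma(spec.L, 1.0 / spec.L, size=shape)
    if spec.family == "rayleigh":
        return rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)
    if spec.family == "gaussian":
        eta = 1.0 + rng.normal(0.0, np.sqrt(spec.sigma2), size=shape)
        return np.maximum(eta, 1e-8)
    if spec.family == "speckle_variance":
        L = max(1, int(round(1.0 / spec.sigma2)))
        return rng.gamma(L, 1.0 / L, size=shape)
    raise ValueError(f"unknown noise family {spec.family!r}")


def degrade(u, psf: Psf, spec: NoiseSpec):
    """Degrade a clean image:  f = (H u) . eta, floored at the positivity
    floor.  Returns (f, eta) so tests can introspect the realized noise."""
    pix = as_pixels(u)
    n_max = u.N_max if isinstance(u, ImageGrid) else 255.0
    if np.any(pix < EPS_POS * n_max - 1e-12):
        raise ValueError("clean image must respect the positivity floor")
    blurred = as_pixels(apply_blur(pix, psf))
    eta = sample_noise(pix.shape, spec)
    f = np.maximum(blurred * eta, EPS_POS * n_max)
    if isinstance(u, ImageGrid):
        return ImageGrid(f, N_max=u.N_max), eta
    return f, eta


# ---------------------------------------------------------------------------
# Cross-channel blur

#: the nine kernels used for cross-channel blurring experiments:
#: motion M(length, angle), gaussian G(hsize, sigma), average A(hsize).
CROSS_CHANNEL_KERNELS = [
    ("motion", {"length": 11, "angle": 45}),
    ("motion", {"length": 21, "angle": 90}),
    ("motion", {"length": 41, "angle": 135}),
    ("gaussian", {"hsize": 7, "sigma": 5}),
    ("gaussian", {"hsize": 9, "sigma": 5}),
    ("gaussian", {"hsize": 11, "sigma": 5}),
    ("average", {"hsize": 13}),
    ("average", {"hsize": 15}),
    ("average", {"hsize": 17}),
]

#: cross-channel weight matrix used in the color experiments
CROSS_CHANNEL_W = np.array([[0.71, 0.15, 0.15],
                            [0.12, 0.80, 0.20],
                            [0.30, 0.30, 0.60]])


def make_cross_channel_blur(W: np.ndarray, seed: int = 0) -> CrossChannelBlur:
    """Assign the nine stock kernels to the m x m kernel grid by a seeded
    random permutation and attach the weight matrix W.  Each kernel is
    normalized before weighting; W = identity gives pure within-channel
    blurring."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    m = W.shape[0]
    if m * m > len(CROSS_CHANNEL_KERNELS):
        raise ValueError("weight matrix larger than the stock kernel set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(CROSS_CHANNEL_KERNELS))[: m * m]
    psfs = [make_psf(BlurSpec(*CROSS_CHANNEL_KERNELS[i])) for i in order]
    kernels = [[psfs[i * m + j] for j in range(m)] for i in range(m)]
    return CrossChannelBlur(kernels=kernels, weights=W)


def apply_cross_channel_blur(u, blur: CrossChannelBlur):
    """Blur an m-channel image with channel mixing:
    out_k = sum_l w[k,l] (K_kl * u_l)."""
    pix = as_pixels(u)
    m = blur.n_channels
    if pix.ndim != 3 or pix.shape[0] != m:
        raise ValueError("channel count mismatch with weight matrix")
    out = np.zeros_like(pix)
    for k in range(m):
        for l in range(m):
            w = blur.weights[k, l]
            if w == 0.0:
                continue
            out[k] += w * as_pixels(apply_blur(pix[l], blur.kernels[k][l]))
    if isinstance(u, ImageGrid):
        return ImageGrid(out, N_max=u.N_max)
    return out


def cross_channel_otf(blur: CrossChannelBlur, shape) -> np.ndarray:
    """Stack of weighted transfer functions, shape (m, m, *rfft grid)."""
    m = blur.n_channels
    first = psf_otf(blur.kernels[0][0], shape)
    H = np.zeros((m, m) + first.shape, dtype=complex)
    for k in range(m):
        for l in range(m):
            H[k, l] = blur.weights[k, l] * psf_otf(blur.kernels[k][l], shape)
    return H


# ---------------------------------------------------------------------------
# Test images

# Shepp-Logan ellipse tables: (intensity, a, b, x0, y0, phi_degrees) on the
# unit square [-1, 1]^2.  "standard" is the original low-contrast head
# phantom; "modified" is the higher-contrast variant most toolboxes return
# by default.
_SHEPP_GEOMETRY = [
    (0.69, 0.92, 0.0, 0.0, 0.0),
    (0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (0.1100, 0.3100, 0.22, 0.0, -18.0),
    (0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.0230, 0.0460, 0.06, -0.605, 0.0),
]
_SHEPP_INTENSITY = {
    "standard": [1.0, -0.98, -0.02, -0.02, 0.01, 0.01, 0.01, 0.01, 0.01,
                 0.01],
    "modified": [1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
}


def shepp_logan(n: int, variant: str = "standard") -> np.ndarray:
    """Shepp-Logan head phantom on an n x n grid, values in [0, 1]."""
    inten = _SHEPP_INTENSITY[variant]
    c = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    # axis 0 is the row index (top-down); the phantom's y axis points up
    y = -c[:, None]
    x = c[None, :]
    img = np.zeros((n, n))
    for A, (a, b, x0, y0, phi) in zip(inten, _SHEPP_GEOMETRY):
        th = np.deg2rad(phi)
        xr = (x - x0) * np.cos(th) + (y - y0) * np.sin(th)
        yr = -(x - x0) * np.sin(th) + (y - y0) * np.cos(th)
        img += A * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return np.clip(img, 0.0, 1.0)


def make_test_image(kind: str, n: int = 256, N_max: float = 255.0,
                    **kwargs) -> ImageGrid:
    """Programmatic test images.

    phantom: Shepp-Logan ellipse composition scaled to [eps_pos, N_max]
    (``variant`` keyword selects the original 'standard' intensity table,
    the default, or the high-contrast 'modified' one).
    constant: uniform image at ``value`` (default N_max/2).
    affine_ramp: u(i, j) = a*i + b*j + c, rescaled to [eps_pos, N_max].
    piecewise_constant: 4x4 block pattern for staircase tests.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    floor = EPS_POS * N_max
    if kind == "phantom":
        base = shepp_logan(n, kwargs.get("variant", "standard"))
        pix = floor + base * (N_max - floor)
    elif kind == "constant":
        pix = np.full((n, n), kwargs.get("value", N_max / 2.0))
    elif kind == "affine_ramp":
        a = kwargs.get("a", 1.0)
        b = kwargs.get("b", 0.5)
        c = kwargs.get("c", 0.0)
        i = np.arange(n)[:, None]
        j = np.arange(n)[None, :]
        pix = a * i + b * j + c
        lo, hi = pix.min(), pix.max()
        if hi > lo:
            pix = floor + (pix - lo) / (hi - lo) * (N_max - floor)
        else:
            pix = np.full_like(pix, N_max / 2.0)
    elif kind == "piecewise_constant":
        rng = np.random.default_rng(kwargs.get("seed", 0))
        levels = rng.uniform(0.15, 0.95, size=(4, 4)) * N_max
        block = n // 4
        pix = np.kron(levels, np.ones((block, block)))
        pix = pix[:n, :n]
        if pix.shape != (n, n):  # n not divisible by 4: pad by edge values
            full = np.full((n, n), levels[-1, -1])
            full[: pix.shape[0], : pix.shape[1]] = pix
            pix = full
    else:
        raise ValueError(f"unknown test image kind {kind!r}")
    return ImageGrid(np.maximum(pix, floor), N_max=N_max)
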