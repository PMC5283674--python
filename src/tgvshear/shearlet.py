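"""Band-limited directional (shearlet-type) Parseval frame.

The system is built entirely in the frequency domain from Meyer-window
profiles: a radial partition into one low-pass band plus ``n_scales``
dyadic annuli, and within each annulus an angular partition whose number of
directions grows with scale following the parabolic-scaling rule of
shearlet systems (directions double every other scale, covering both
frequency cones).  Squared-cosine (Meyer) transitions make the squares of
all windows sum to one at every frequency, so the filter bank {H_j} is a
Parseval frame: the adjoint transform is the inverse, the property the ADMM
solver's Fourier-diagonal u-update relies on.

Every filter is real and even under frequency negation, hence real images
map to real coefficient bands and all transforms run on the half-plane
real-FFT grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import fft as _fft

from . import _fourier


def _meyer_ramp(x: np.ndarray) -> np.ndarray:
    """Smooth 0->1 ramp on [0, 1] with sin^2+cos^2 complementarity."""
    x = np.clip(x, 0.0, 1.0)
    v = x ** 4 * (35.0 - 84.0 * x + 70.0 * x ** 2 - 20.0 * x ** 3)
    return np.sin(0.5 * np.pi * v)


@dataclass
class ShearletSystem:
    """Frequency-response bank H_j (j=0 low-pass, j>=1 directional)."""

    filters: np.ndarray      # (n_bands, m1, m2) full-grid real responses
    n_scales: int
    shape: tuple[int, int]

    @property
    def n_bands(self) -> int:
        return self.filters.shape[0]

    @property
    def filters_half(self) -> np.ndarray:
        if not hasattr(self, "_half"):
            m2 = self.shape[1]
            object.__setattr__(self, "_half",
                               np.ascontiguousarray(
                                   self.filters[:, :, : m2 // 2 + 1]))
        return self._half


@dataclass
class ShearletCoeffs:
    """Stack of n_bands coefficient arrays, each m1 x m2 (gray levels)."""

    bands: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]


def n_directions(scale: int) -> int:
    """Directions at a given scale (1-based): 8, 8, 16, 16, 32, ..."""
    return 8 * 2 ** ((scale - 1) // 2)


def build_system(m1: int, m2: int, n_scales: int = 4) -> ShearletSystem:
    """Construct the Meyer-window band-limited directional frame.

    Requires min(m1, m2) >= 2**(n_scales + 1) so the innermost annulus is
    resolvable on the grid.
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if min(m1, m2) < 2 ** (n_scales + 1):
        raise ValueError(
            f"image {m1}x{m2} too small for {n_scales} scales "
            f"(need min side >= {2 ** (n_scales + 1)})")

    # normalized radius: 1.0 at the Nyquist frequency on the axes
    w1 = _fft.fftfreq(m1) / 0.5
    w2 = _fft.fftfreq(m2) / 0.5
    W1, W2 = np.meshgrid(w1, w2, indexing="ij")
    r = np.hypot(W1, W2)
    theta = np.mod(np.arctan2(W2, W1), np.pi)  # slope-symmetric angle

    # radial Meyer partition: knots 2^-S, ..., 1/2, 1; the outermost band
    # plateaus at 1 beyond the last knot so the grid corners are covered
    knots = [2.0 ** (-(n_scales - s)) for s in range(n_scales + 1)]
    low = np.sqrt(np.clip(1.0 - _meyer_ramp(
        (r - knots[0]) / (knots[1] - knots[0])) ** 2, 0.0, 1.0))
    radial_bands = []
    for s in range(1, n_scales + 1):
        rise = _meyer_ramp((r - knots[s - 1]) / (knots[s] - knots[s - 1]))
        if s < n_scales:
            fall = np.sqrt(np.clip(1.0 - _meyer_ramp(
                (r - knots[s]) / (knots[s + 1] - knots[s])) ** 2, 0.0, 1.0))
        else:
            fall = 1.0  # outermost band extends to the corners
        radial_bands.append(rise * fall)

    filters = [low]
    for s, rad in enumerate(radial_bands, start=1):
        nd = n_directions(s)
        h = np.pi / nd
        for k in range(nd):
            center = k * h
            d = np.abs(theta - center)
            d = np.minimum(d, np.pi - d)  # angular distance mod pi
            rise = _meyer_ramp(1.0 - d / h)
            filters.append(rad * rise)
    filters = np.stack(filters)

    # enforce exact evenness under frequency negation (the angular windows
    # break it on the self-conjugate Nyquist lines of even grids), then
    # kill the float residue of the partition so Parseval is exact
    reflected = np.roll(filters[:, ::-1, ::-1], shift=(1, 1), axis=(1, 2))
    filters = 0.5 * (filters + reflected)
    norm = np.sqrt(np.sum(filters ** 2, axis=0))
    filters /= norm

    return ShearletSystem(filters=filters, n_scales=n_scales,
                          shape=(m1, m2))


@lru_cache(maxsize=8)
def cached_system(m1: int, m2: int, n_scales: int) -> ShearletSystem:
    """Per-shape cache; solver iterations reuse one system."""
    return build_system(m1, m2, n_scales)


def forward(u: np.ndarray, sys: ShearletSystem) -> ShearletCoeffs:
    """Band j = IFFT(H_j . FFT(u)); real output for real input."""
    u = np.asarray(u, dtype=float)
    if u.shape != sys.shape:
        raise ValueError("image shape does not match the system")
    U = _fourier.rfft2(u)
    bands = np.empty((sys.n_bands,) + sys.shape)
    for j in range(sys.n_bands):
        bands[j] = _fourier.irfft2(sys.filters_half[j] * U, sys.shape)
    return ShearletCoeffs(bands=bands)


def save_coeffs(c: ShearletCoeffs, path) -> None:
    """Export a coefficient stack for inspection: multi-page float TIFF
    (``.tif``/``.tiff``) or a raw ``.npy`` array archive."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import imageio.v3 as iio
        iio.imwrite(path, c.bands.astype(np.float32))
    elif path.endswith(".npy"):
        np.save(path, c.bands)
    else:
        raise ValueError("unsupported export format (use .tif/.tiff/.npy)")


def adjoint(c: ShearletCoeffs, sys: ShearletSystem) -> np.ndarray:
    """Sum_j IFFT(H_j . FFT(c_j)); inverts ``forward`` (Parseval frame)."""
    if c.n_bands != sys.n_bands:
        raise ValueError("band count does not match the system")
    acc = np.zeros((sys.shape[0], sys.shape[1] // 2 + 1), dtype=complex)
    for j in range(sys.n_bands):
        acc += sys.filters_half[j] * _fourier.rfft2(c.bands[j])
    return _fourier.irfft2(acc, sys.shape)
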