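"""Image quality measures: PSNR, global SSIM, relative error, SNR.

SSIM here is the single *global* statistic computed from whole-image means,
variances and covariance — deliberately not the common windowed/averaged
SSIM — because that is the form the restoration benchmarks in this package
report.  Values therefore differ from ``skimage.metrics.structural_similarity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .degrade import as_pixels


@dataclass
class MetricConstants:
    """Peak gray level and SSIM stabilizers a1 = (0.01 N)^2, a2 = (0.03 N)^2."""

    N_max: float = 255.0
    a1: float = field(default=None)
    a2: float = field(default=None)

    def __post_init__(self):
        if self.a1 is None:
            self.a1 = (0.01 * self.N_max) ** 2
        if self.a2 is None:
            self.a2 = (0.03 * self.N_max) ** 2
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("SSIM stabilizers must be positive")


def _pair(u_hat, u):
    a, b = as_pixels(u_hat), as_pixels(u)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return a, b


def psnr(u_hat, u, N_max: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10 log10(N^2 / MSE) in dB.

    Identical images return ``inf``.
    """
    a, b = _pair(u_hat, u)
    mse = np.mean((a - b) ** 2)
    if mse == 0.0:
        return np.inf
    return float(10.0 * np.log10(N_max ** 2 / mse))


def ssim_global(u_hat, u, consts: MetricConstants | None = None) -> float:
    """Global structural similarity from whole-image moments (not windowed)."""
    if consts is None:
        consts = MetricConstants()
    a, b = _pair(u_hat, u)
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = np.mean((a - mu_a) * (b - mu_b))
    num = (2.0 * mu_a * mu_b + consts.a1) * (2.0 * cov + consts.a2)
    den = (mu_a ** 2 + mu_b ** 2 + consts.a1) * (var_a + var_b + consts.a2)
    return float(num / den)


def rel_err(u_hat, u, squared: bool = True) -> float:
    """Relative error ||u_hat - u||^2 / ||u||^2 (or the unsquared ratio)."""
    a, b = _pair(u_hat, u)
    den = np.sum(b ** 2)
    if den == 0.0:
        raise ValueError("reference image is identically zero")
    ratio = np.sum((a - b) ** 2) / den
    return float(ratio if squared else np.sqrt(ratio))


def snr(u_hat, u) -> float:
    """Signal-to-noise ratio 10 log10(||u - mean(u)||^2 / ||u - u_hat||^2)."""
    a, b = _pair(u_hat, u)
    num = np.sum((b - b.mean()) ** 2)
    if num == 0.0:
        raise ValueError("reference image is constant")
    den = np.sum((b - a) ** 2)
    if den == 0.0:
        return np.inf
    return float(10.0 * np.log10(num / den))
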