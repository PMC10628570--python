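"""Reconstruction quality metrics: RMSE, HFEN, and SSIM.

RMSE is the root mean square voxel difference. HFEN (high-frequency error
norm) compares the two images after Laplacian-of-Gaussian filtering and is
normalized by the filtered reference, so it is asymmetric in its arguments:
the first argument is the reference ("label") image. SSIM is the global
structural similarity index computed from whole-image means, variances and
covariance; a sliding-window mode (mean of local SSIM values) is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MetricConfig", "rmse", "hfen", "ssim", "log_of_gaussian_kernel"]


@dataclass
class MetricConfig:
    """Tunables for HFEN and SSIM.

    log_sigma / log_size: the LoG filter width (voxels) and odd kernel
    extent (HFEN literature convention: 15, sigma 1.5). c1, c2: SSIM
    stabilizers; if None they default to (0.01 L)^2 and (0.03 L)^2 with
    L the dynamic range of the reference image.
    """

    log_sigma: float = 1.5
    log_size: int = 15
    c1: float | None = None
    c2: float | None = None
    dynamic_range: float | None = None

    def __post_init__(self) -> None:
        if self.log_size % 2 != 1:
            raise ValueError("log_size must be odd")
        if self.c1 is not None and self.c1 <= 0:
            raise ValueError("c1 must be > 0")
        if self.c2 is not None and self.c2 <= 0:
            raise ValueError("c2 must be > 0")


def _check_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean square error sqrt(sum (x - y)^2 / n_voxels)."""
    x, y = _check_shapes(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def log_of_gaussian_kernel(size: int, sigma: float, ndim: int) -> np.ndarray:
    """Sampled Laplacian-of-Gaussian kernel on a size^ndim grid."""
    ax = np.arange(size) - size // 2
    grids = np.meshgrid(*([ax] * ndim), indexing="ij")
    r2 = sum(g.astype(float) ** 2 for g in grids)
    s2 = sigma ** 2
    g = np.exp(-r2 / (2 * s2))
    log = (r2 - ndim * s2) / (s2 ** 2) * g
    return log - log.mean()  # zero-sum so flat regions map to zero


def _log_filter(img: np.ndarray, cfg: MetricConfig) -> np.ndarray:
    ker = log_of_gaussian_kernel(cfg.log_size, cfg.log_sigma, img.ndim)
    return ndimage.convolve(img, ker, mode="reflect")


def hfen(x: np.ndarray, y: np.ndarray, cfg: MetricConfig | None = None) -> float:
    """High-frequency error norm ||LoG(x) - LoG(y)||_F^2 / ||LoG(x)||_F^2.

    ``x`` is the reference (label) image; multiple image pairs can be
    averaged by the caller. Raises on a flat reference (zero denominator).
    """
    cfg = cfg or MetricConfig()
    x, y = _check_shapes(x, y)
    lx = _log_filter(x, cfg)
    ly = _log_filter(y, cfg)
    den = float(np.sum(lx ** 2))
    # flat reference: LoG is zero up to round-off of the zero-sum kernel
    if den <= 1e-24 * x.size * max(1.0, float(np.max(np.abs(x))) ** 2):
        raise ValueError("reference image is flat: LoG(x) is identically zero")
    return float(np.sum((lx - ly) ** 2) / den)


def _global_ssim(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


def ssim(x: np.ndarray, y: np.ndarray, cfg: MetricConfig | None = None,
         sliding_window: bool = False, window: int = 7) -> float:
    """Structural similarity index from global (or windowed) statistics.

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
           / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)).
    """
    cfg = cfg or MetricConfig()
    x, y = _check_shapes(x, y)
    L = cfg.dynamic_range
    if L is None:
        L = float(x.max() - x.min())
        if L == 0:
            L = 1.0
    c1 = cfg.c1 if cfg.c1 is not None else (0.01 * L) ** 2
    c2 = cfg.c2 if cfg.c2 is not None else (0.03 * L) ** 2
    if not sliding_window:
        return _global_ssim(x, y, c1, c2)
    # mean of local SSIM over a sliding boxcar window
    def box(a):
        return ndimage.uniform_filter(a, size=window, mode="reflect")
    mx, my = box(x), box(y)
    vx = box(x * x) - mx ** 2
    vy = box(y * y) - my ** 2
    cov = box(x * y) - mx * my
    local = ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2))
    return float(local.mean())
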