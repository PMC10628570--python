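"""Resting-state preprocessing and regional homogeneity (ReHo) mapping.

ReHo quantifies local synchronization of spontaneous BOLD fluctuations as
Kendall's coefficient of concordance (KCC, W) between each voxel's time
series and its neighbors (26 surrounding voxels by default). The standard
processing order is slice-timing correction, motion QC (subjects exceeding
1.5 mm translation or 1.5 deg rotation are excluded), band-pass filtering
(0.01-0.08 Hz), ReHo mapping, standardization by the whole-brain mean KCC,
and 6 mm Gaussian smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .volgrid import BoldSeries, MaskVolume, Volume

__all__ = [
    "MotionTrace",
    "MotionQCRecord",
    "RehoConfig",
    "slice_timing_correct",
    "motion_qc",
    "bandpass_filter",
    "kendalls_w",
    "reho_map",
    "standardize_reho",
]


@dataclass
class MotionTrace:
    """Per-volume rigid parameters: 3 translations (mm), 3 rotations (deg)."""

    params: np.ndarray  # (n_volumes, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float).reshape(-1, 6)
        if len(self.params) == 0:
            raise ValueError("motion trace is empty")

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]

    @classmethod
    def read(cls, path: str | Path) -> "MotionTrace":
        return cls(np.loadtxt(path))

    def write(self, path: str | Path) -> None:
        np.savetxt(path, self.params, fmt="%.6f")


@dataclass
class MotionQCRecord:
    excluded: bool
    offending_volumes: list[int]
    max_translation_mm: float
    max_rotation_deg: float


@dataclass
class RehoConfig:
    """ReHo pipeline settings.

    neighborhood: cluster size including the center voxel (7, 19 or 27;
    27 means the voxel plus the 26 voxels around it). band_hz is the
    retained frequency band; motion limits are (mm, degrees).
    """

    neighborhood: int = 27
    band_hz: tuple[float, float] = (0.01, 0.08)
    smooth_fwhm_mm: float = 6.0
    motion_limits: tuple[float, float] = (1.5, 1.5)

    def __post_init__(self) -> None:
        if self.neighborhood not in (7, 19, 27):
            raise ValueError("neighborhood must be 7, 19 or 27")
        lo, hi = self.band_hz
        if not (0 <= lo < hi):
            raise ValueError("band must satisfy 0 <= low < high")


def slice_timing_correct(series: BoldSeries, slice_order: list[int] | np.ndarray,
                         ref_slice: int = 0) -> BoldSeries:
    """Shift each slice's time series to the reference slice's acquisition time.

    ``slice_order`` lists slices in acquisition order (a permutation of
    0..n_slices-1); slices are assumed evenly spread over one TR. Linear
    temporal interpolation with held endpoints.
    """
    n_slices = series.data.shape[2]
    order = np.asarray(slice_order, dtype=int)
    if sorted(order.tolist()) != list(range(n_slices)):
        raise ValueError("slice_order must be a permutation of all slices")
    n_t = series.n_timepoints
    # acquisition slot (fraction of TR) per slice
    slot = np.empty(n_slices)
    slot[order] = np.arange(n_slices) / n_slices
    out = np.empty_like(series.data, dtype=float)
    base = np.arange(n_t, dtype=float)
    for z in range(n_slices):
        delta = slot[ref_slice] - slot[z]  # in volumes
        pos = np.clip(base + delta, 0, n_t - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, n_t - 1)
        frac = pos - lo
        sl = series.data[:, :, z, :]
        out[:, :, z, :] = sl[..., lo] * (1 - frac) + sl[..., hi] * frac
    return series.with_data(out)


def motion_qc(trace: MotionTrace, limits: tuple[float, float] = (1.5, 1.5)) -> MotionQCRecord:
    """Exclude a subject iff any |translation| > limit_mm or |rotation| > limit_deg.

    The comparison is a strict inequality: a volume at exactly the limit
    is retained.
    """
    t_lim, r_lim = limits
    t_bad = np.any(np.abs(trace.translations) > t_lim, axis=1)
    r_bad = np.any(np.abs(trace.rotations) > r_lim, axis=1)
    bad = np.flatnonzero(t_bad | r_bad)
    return MotionQCRecord(
        excluded=bool(len(bad)),
        offending_volumes=bad.tolist(),
        max_translation_mm=float(np.abs(trace.translations).max()),
        max_rotation_deg=float(np.abs(trace.rotations).max()),
    )


def bandpass_filter(series: BoldSeries, band_hz: tuple[float, float] = (0.01, 0.08)) -> BoldSeries:
    """Zero-phase frequency-domain band-pass; the series mean is removed."""
    lo, hi = band_hz
    nyq = 1.0 / (2.0 * series.tr_seconds)
    if not (0 <= lo < hi <= nyq + 1e-12):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq:.4f}]")
    n_t = series.n_timepoints
    freqs = np.fft.rfftfreq(n_t, d=series.tr_seconds)
    keep = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    spec = np.fft.rfft(series.data, axis=3)
    spec[..., ~keep] = 0.0
    return series.with_data(np.fft.irfft(spec, n=n_t, axis=3))


def kendalls_w(series_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance over k series of n time points.

    Each row is ranked over time (midranks for ties); with R_t the sum of
    ranks across series at time t, W = 12 * sum_t (R_t - R_bar)^2
    / (k^2 (n^3 - n)). W = 1 means all series perfectly co-ranked.
    """
    m = np.asarray(series_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a k x n matrix with k >= 2, n >= 2")
    k, n = m.shape
    ranks = rankdata(m, axis=1)
    R = ranks.sum(axis=0)
    W = 12.0 * np.sum((R - R.mean()) ** 2) / (k ** 2 * (n ** 3 - n))
    return float(W)


_NEIGHBORHOODS: dict[int, np.ndarray] = {}


def _neighborhood_kernel(size: int) -> np.ndarray:
    if size not in _NEIGHBORHOODS:
        k = np.zeros((3, 3, 3), dtype=float)
        off = np.indices((3, 3, 3)) - 1
        cheb = np.abs(off).sum(axis=0)
        if size == 7:
            k[cheb <= 1] = 1  # center + 6 faces
        elif size == 19:
            k[cheb <= 2] = 1  # + 12 edges
        else:
            k[:] = 1  # full 27
        _NEIGHBORHOODS[size] = k
    return _NEIGHBORHOODS[size]


def reho_map(series: BoldSeries, mask: MaskVolume,
             cfg: RehoConfig | None = None) -> Volume:
    """Voxelwise Kendall's W over each voxel's neighborhood cluster.

    Neighbors outside the mask or grid are dropped; voxels left with fewer
    than 2 series get ReHo 0. Output is zero outside the mask.

    The computation is vectorized: per-voxel temporal midranks are summed
    over the neighborhood by 3D convolution, and W is evaluated from the
    per-time rank sums in closed form.
    """
    cfg = cfg or RehoConfig()
    mdat = mask.data.astype(bool)
    if not mdat.any():
        raise ValueError("mask is empty")
    n_t = series.n_timepoints
    kernel = _neighborhood_kernel(cfg.neighborhood)

    ranks = rankdata(series.data, axis=3).astype(np.float32)
    ranks *= mdat[..., None]

    # k = number of in-mask series contributing at each voxel
    kcount = ndimage.convolve(mdat.astype(np.float32), kernel, mode="constant")
    kcount = np.round(kcount)

    # per-time rank sums R_t via convolution, accumulate sum and sum of squares
    S1 = np.zeros(mdat.shape, dtype=np.float64)
    S2 = np.zeros(mdat.shape, dtype=np.float64)
    for t in range(n_t):
        Rt = ndimage.convolve(ranks[..., t], kernel, mode="constant")
        S1 += Rt
        S2 += Rt.astype(np.float64) ** 2
    # sum_t (R_t - mean)^2 = S2 - S1^2 / n
    ss = S2 - S1 ** 2 / n_t
    with np.errstate(divide="ignore", invalid="ignore"):
        W = 12.0 * ss / (kcount ** 2 * (n_t ** 3 - n_t))
    W[kcount < 2] = 0.0
    W[~mdat] = 0.0
    W = np.clip(W, 0.0, 1.0)
    return Volume(W, series.spacing, series.affine.copy(), units="KCC")


def standardize_reho(reho: Volume, mask: MaskVolume) -> Volume:
    """Divide each voxel's KCC by the whole-brain mean KCC (mask mean = 1)."""
    mdat = mask.data.astype(bool)
    mean = float(reho.data[mdat].mean())
    if mean <= 0:
        raise ValueError("mask-mean ReHo must be positive")
    out = np.where(mdat, reho.data / mean, 0.0)
    return reho.with_data(out, units="KCC/mean")
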