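"""Voxelwise two-group comparison with Monte-Carlo cluster-extent correction.

A pooled-variance two-sample t-test is run per voxel; family-wise error is
controlled in the AlphaSim style: null Gaussian fields with the assumed
smoothness are simulated on the analysis mask, thresholded at the voxel
p-value, and the distribution of the maximum cluster extent yields the
minimum extent whose family-wise probability under the null is at most
alpha. Suprathreshold clusters at or above that extent are reported with
their peak world coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volgrid import MaskVolume, Volume, fwhm_to_sigma

__all__ = [
    "StatMap",
    "ClusterTable",
    "voxelwise_ttest",
    "alphasim_threshold",
    "report_clusters",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """Per-voxel t statistic, two-sided p, and definedness flags."""

    t: np.ndarray
    p: np.ndarray
    df: int
    mask: MaskVolume
    defined: np.ndarray  # False where the statistic is undefined (zero variance)


@dataclass
class ClusterTable:
    """Cluster report in the layout label / peak XYZ / extent / peak t /
    direction / corrected."""

    rows: pd.DataFrame

    COLUMNS = ["label", "peak_x", "peak_y", "peak_z", "extent", "peak_t",
               "direction", "corrected"]

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def empty(cls) -> "ClusterTable":
        return cls(pd.DataFrame(columns=cls.COLUMNS))


def voxelwise_ttest(group_a: np.ndarray, group_b: np.ndarray,
                    mask: MaskVolume) -> StatMap:
    """Two-sample pooled-variance t-test per voxel (A minus B).

    Stacks are 4D with subjects on the last axis. Voxels where both groups
    have zero variance are flagged undefined rather than zeroed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[:3] != b.shape[:3] or a.shape[:3] != mask.data.shape:
        raise ValueError("group stacks and mask must share a grid")
    n_a, n_b = a.shape[3], b.shape[3]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    df = n_a + n_b - 2
    ma, mb = a.mean(axis=3), b.mean(axis=3)
    va = a.var(axis=3, ddof=1)
    vb = b.var(axis=3, ddof=1)
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    defined = (se > 0) & mask.data.astype(bool)
    t = np.zeros_like(ma)
    t[defined] = (ma - mb)[defined] / se[defined]
    p = np.ones_like(ma)
    p[defined] = 2.0 * stats.t.sf(np.abs(t[defined]), df)
    return StatMap(t=t, p=p, df=df, mask=mask, defined=defined)


def alphasim_threshold(mask: MaskVolume, fwhm_mm: float, voxel_p: float = 0.005,
                       alpha: float = 0.05, n_iter: int = 1000, seed: int = 0,
                       connectivity: int = 6) -> int:
    """Minimum cluster extent controlling family-wise error at ``alpha``.

    Simulates ``n_iter`` Gaussian null fields on the mask grid, smooths
    them to ``fwhm_mm``, standardizes within the mask, applies the
    two-sided voxel threshold, and records each iteration's maximum
    cluster size. Returns the smallest extent k with empirical
    P(max cluster >= k) <= alpha.
    """
    if not (0 < voxel_p < 1 and 0 < alpha < 1):
        raise ValueError("voxel_p and alpha must be in (0, 1)")
    if n_iter < 200:
        raise ValueError("n_iter must be >= 200 for a usable tail estimate")
    rng = np.random.default_rng(seed)
    mdat = mask.data.astype(bool)
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / s for s in mask.spacing]
    z_th = stats.norm.ppf(1.0 - voxel_p / 2.0)
    structure = _STRUCTURES[connectivity]

    maxima = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        field = rng.standard_normal(mdat.shape)
        if fwhm_mm > 0:
            field = ndimage.gaussian_filter(field, sigma_vox, mode="reflect")
        vals = field[mdat]
        field = (field - vals.mean()) / vals.std()
        supra = (np.abs(field) >= z_th) & mdat
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab == 0:
            maxima[i] = 0
        else:
            maxima[i] = int(np.bincount(labels.ravel())[1:].max())

    for k in range(1, maxima.max() + 2):
        if (maxima >= k).mean() <= alpha:
            if alpha < 1.0 / n_iter and k > maxima.max():
                import warnings
                warnings.warn(f"alpha={alpha} below 1/n_iter resolution; "
                              "extent is an upper bound", stacklevel=2)
            return k
    return int(maxima.max() + 1)  # pragma: no cover


def report_clusters(stat: StatMap, voxel_p: float, min_extent: int,
                    affine: np.ndarray | None = None,
                    connectivity: int = 6) -> ClusterTable:
    """Connected suprathreshold components of size >= min_extent.

    Positive (increase) and negative (decrease) excursions are labeled
    separately; peaks are mapped voxel -> world mm through the affine.
    """
    if affine is None:
        affine = stat.mask.affine
    t_th = stats.t.ppf(1.0 - voxel_p / 2.0, stat.df)
    structure = _STRUCTURES[connectivity]
    rows = []
    label_id = 0
    for direction, supra in (("increase", (stat.t >= t_th) & stat.defined),
                             ("decrease", (stat.t <= -t_th) & stat.defined)):
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            comp = labels == lab
            extent = int(comp.sum())
            if extent < min_extent:
                continue
            label_id += 1
            tvals = np.where(comp, np.abs(stat.t), -np.inf)
            peak = np.unravel_index(np.argmax(tvals), tvals.shape)
            world = affine @ np.array([*peak, 1.0])
            rows.append({
                "label": label_id,
                "peak_x": float(world[0]), "peak_y": float(world[1]),
                "peak_z": float(world[2]),
                "extent": extent,
                "peak_t": float(stat.t[peak]),
                "direction": direction,
                "corrected": True,
            })
    if not rows:
        return ClusterTable.empty()
    return ClusterTable(pd.DataFrame(rows, columns=ClusterTable.COLUMNS))
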