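"""Volume data model, NIfTI-1 I/O, and Gaussian smoothing.

Every stage of the toolkit operates on :class:`Volume` (3D scalar grid),
:class:`BoldSeries` (4D time series) or :class:`MaskVolume` (binary grid).
A volume owns its voxel spacing in mm and a 4x4 grid-to-world affine;
voxel indices are 0-based and world coordinates are obtained by applying
the affine to homogeneous voxel indices (RAS-oriented by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BoldSeries",
    "MaskVolume",
    "read_volume",
    "write_volume",
    "gaussian_smooth",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a full-width-at-half-maximum to a Gaussian sigma (same units)."""
    return float(fwhm) / _FWHM_PER_SIGMA


def _default_affine(spacing: tuple[float, ...]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing[:3]
    return aff


@dataclass
class Volume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
    spacing : voxel size per axis in mm, all entries > 0
    affine : 4x4 grid-to-world map (defaults to a diagonal scaling by spacing)
    units : free-text label for the voxel values (e.g. "ppm", "a.u.")
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume requires 3D data, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray, units: str | None = None) -> "Volume":
        """New Volume on the same grid with different voxel values."""
        return Volume(data, self.spacing, self.affine.copy(),
                      self.units if units is None else units)

    def same_grid(self, other: "Volume") -> bool:
        return (self.data.shape[:3] == other.data.shape[:3]
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.affine, other.affine))


@dataclass
class BoldSeries:
    """A 4D BOLD time series (x, y, z, t) sharing the Volume grid model."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BoldSeries requires 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BoldSeries needs at least 2 time points")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def frame(self, t: int) -> Volume:
        return Volume(self.data[..., t], self.spacing, self.affine.copy())

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data, self.spacing, self.affine.copy(), self.tr_seconds)


@dataclass
class MaskVolume:
    """Binary 3D mask on the same grid as the Volume it qualifies."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"MaskVolume requires 3D data, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(bool)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def read_volume(path: str | Path) -> Volume | BoldSeries:
    """Load a NIfTI-1 file as a Volume (3D) or BoldSeries (4D).

    The TR of a 4D file is taken from pixdim[4] of the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises ImageFileError subclasses
        raise ValueError(f"not a NIfTI file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    if any(d == 0 for d in data.shape):
        raise ValueError(f"zero-sized dimension in {path}: shape {data.shape}")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    affine = np.asarray(img.affine, dtype=float)
    if data.ndim == 3:
        return Volume(data, spacing, affine)
    if data.ndim == 4:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return BoldSeries(data, spacing, affine, tr_seconds=tr)
    raise ValueError(f"unsupported dimensionality {data.ndim} in {path}")


def write_volume(vol: Volume | BoldSeries | MaskVolume, path: str | Path) -> None:
    """Write a volume to a NIfTI-1 file (.nii or .nii.gz)."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, MaskVolume):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), vol.affine)
    zooms = list(vol.spacing)
    if isinstance(vol, BoldSeries):
        zooms.append(vol.tr_seconds)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def gaussian_smooth(vol: Volume, fwhm_mm: float | tuple[float, float, float]) -> Volume:
    """Gaussian smoothing with per-axis FWHM in mm, reflective boundary.

    sigma per axis is fwhm / (2*sqrt(2 ln 2)) divided by the voxel spacing.
    Reflective padding conserves the image mean (to ~1e-6 relative).
    """
    from scipy import ndimage

    if np.isscalar(fwhm_mm):
        fwhm = (float(fwhm_mm),) * 3
    else:
        fwhm = tuple(float(f) for f in fwhm_mm)
    if any(f < 0 for f in fwhm):
        raise ValueError(f"fwhm must be non-negative, got {fwhm}")
    sigma_vox = [fwhm_to_sigma(f) / s for f, s in zip(fwhm, vol.spacing)]
    if all(s == 0 for s in sigma_vox):
        return vol.with_data(vol.data.copy())
    out = ndimage.gaussian_filter(vol.data.astype(float), sigma=sigma_vox, mode="reflect")
    return vol.with_data(out)
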