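"""Diffusion tensor estimation and FA/MD scalar maps.

The diffusion-weighted signal follows the monoexponential tensor model
S = S0 * exp(-b g^T D g) with D a symmetric 3x3 tensor in mm^2/s. Fitting
is log-linear least squares per voxel; fractional anisotropy (FA) and mean
diffusivity (MD) are the standard eigenvalue summaries, with eigenvalues
clipped at zero so FA stays in [0, 1] under noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volgrid import MaskVolume, Volume

__all__ = [
    "GradientScheme",
    "TensorField",
    "fit_tensor",
    "tensor_scalars",
    "read_scheme",
    "write_scheme",
]

_LOG_FLOOR = 1e-8


@dataclass
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    bvecs rows for b > 0 volumes must be unit norm; b = 0 rows may be zero.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ValueError("bvals and bvecs disagree on volume count")
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted bvecs must be unit norm")
        if not np.any(self.bvals == 0):
            raise ValueError("scheme needs at least one b = 0 volume")

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    def n_unique_directions(self) -> int:
        dirs = self.bvecs[self.bvals > 0]
        if len(dirs) == 0:
            return 0
        # antipodal pairs count once
        canon = np.where(dirs[:, [0]] < 0, -dirs, dirs)
        return len(np.unique(np.round(canon, 6), axis=0))


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors (mm^2/s) plus the S0 map.

    tensors has shape (nx, ny, nz, 6) holding the unique elements in
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) order.
    """

    tensors: np.ndarray
    s0: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def full_matrices(self) -> np.ndarray:
        """(nx, ny, nz, 3, 3) symmetric matrices."""
        t = self.tensors
        out = np.empty(t.shape[:-1] + (3, 3), dtype=float)
        out[..., 0, 0] = t[..., 0]
        out[..., 1, 1] = t[..., 1]
        out[..., 2, 2] = t[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = t[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = t[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = t[..., 5]
        return out


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    """ln S = X beta with beta = (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    b = scheme.bvals
    g = scheme.bvecs
    X = np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])
    return X


def fit_tensor(dwi: np.ndarray, scheme: GradientScheme,
               mask: MaskVolume | np.ndarray | None = None,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
               affine: np.ndarray | None = None) -> TensorField:
    """Log-linear least-squares tensor fit.

    Parameters
    ----------
    dwi : 4D array (x, y, z, n_volumes) of diffusion-weighted signals
    scheme : gradient table matching the last axis of ``dwi``
    mask : optional; voxels outside get zero tensors

    Zero or negative signals are floored at a small positive constant
    before the log so the design stays well posed.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, volumes)")
    if dwi.shape[3] != scheme.n_volumes:
        raise ValueError("dwi volume count does not match scheme")
    if scheme.n_volumes < 7:
        raise ValueError("need at least 7 volumes (6 directions + b0)")
    if scheme.n_unique_directions() < 6:
        raise ValueError("need at least 6 unique gradient directions")

    X = _design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient design: collinear gradient directions")

    shape = dwi.shape[:3]
    if mask is None:
        mdat = np.ones(shape, dtype=bool)
    else:
        mdat = mask.data if isinstance(mask, MaskVolume) else np.asarray(mask, dtype=bool)

    logs = np.log(np.maximum(dwi[mdat], _LOG_FLOOR))  # (n_in, n_vol)
    beta, *_ = np.linalg.lstsq(X, logs.T, rcond=None)  # (7, n_in)

    tensors = np.zeros(shape + (6,), dtype=float)
    s0 = np.zeros(shape, dtype=float)
    tensors[mdat] = beta[1:].T
    s0[mdat] = np.exp(beta[0])
    return TensorField(tensors, s0, spacing, affine)


def tensor_scalars(tf: TensorField) -> tuple[Volume, Volume]:
    """FA and MD maps from a tensor field.

    Eigenvalues are sorted descending and clipped at zero. MD is their mean;
    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||, set to 0 where all
    eigenvalues vanish.
    """
    mats = tf.full_matrices()
    if not np.all(np.isfinite(mats)):
        raise ValueError("tensor field contains non-finite values")
    evals = np.linalg.eigvalsh(mats)  # ascending
    evals = np.clip(evals[..., ::-1], 0.0, None)
    md = evals.mean(axis=-1)
    dev = evals - md[..., None]
    num = np.sqrt((dev ** 2).sum(axis=-1))
    den = np.sqrt((evals ** 2).sum(axis=-1))
    fa = np.zeros_like(md)
    nz = den > 0
    fa[nz] = np.sqrt(1.5) * num[nz] / den[nz]
    fa = np.clip(fa, 0.0, 1.0)
    aff = None if tf.affine is None else tf.affine.copy()
    return (Volume(fa, tf.spacing, aff, units="FA"),
            Volume(md, tf.spacing, None if aff is None else aff.copy(), units="mm^2/s"))


def read_scheme(bvec_path: str | Path, bval_path: str | Path) -> GradientScheme:
    """Read FSL-style bvec (3 x N) and bval (1 x N) text files."""
    bvecs = np.loadtxt(bvec_path)
    bvals = np.loadtxt(bval_path)
    if bvecs.ndim == 2 and bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientScheme(bvals, bvecs)


def write_scheme(scheme: GradientScheme, bvec_path: str | Path, bval_path: str | Path) -> None:
    """Write FSL-style bvec/bval text files (3 rows / 1 row)."""
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.1f")
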