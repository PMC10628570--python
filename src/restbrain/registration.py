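"""Affine and small-deformation nonlinear registration with a Pearson
correlation-coefficient (CC) objective.

The affine stage maximizes CC over up to 12 parameters (translation,
rotation, log-scale, shear) with Nelder-Mead simplex restarts over a
coarse-to-fine image pyramid; rotations act about the fixed-image center.
The nonlinear stage is a fluid-like iterative scheme: images are
standardized within the mask (which makes the sum-of-squares mismatch a
strictly decreasing function of CC, so the same objective is optimized),
per-voxel forces use the demons normalization, the force field is
Gaussian-smoothed (fluid regularization) plus a light smoothing of the
accumulated field (elastic), steps are capped at a fraction of a voxel,
and the displacement-field Jacobian is monitored so the map stays
invertible on essentially all of the mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .volgrid import MaskVolume, Volume, gaussian_smooth

__all__ = [
    "AffineParams",
    "DisplacementField",
    "RegistrationConfig",
    "correlation_coefficient",
    "apply_affine",
    "affine_register",
    "nonlinear_register",
    "apply_field",
    "compose_affine",
]


@dataclass
class AffineParams:
    """World-space affine map w -> matrix @ w + translation (mm units)."""

    matrix: np.ndarray
    translation: np.ndarray
    warning: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.eye(3), np.zeros(3))

    def rotation_angles_deg(self) -> np.ndarray:
        """Euler angles (deg, xyz order) of the rotation part via polar decomposition."""
        u, _, vt = np.linalg.svd(self.matrix)
        R = u @ vt
        if np.linalg.det(R) < 0:
            R = u @ np.diag([1, 1, -1]) @ vt
        sy = np.hypot(R[0, 0], R[1, 0])
        if sy > 1e-9:
            angles = [np.arctan2(R[2, 1], R[2, 2]), np.arctan2(-R[2, 0], sy),
                      np.arctan2(R[1, 0], R[0, 0])]
        else:
            angles = [np.arctan2(-R[1, 2], R[1, 1]), np.arctan2(-R[2, 0], sy), 0.0]
        return np.degrees(angles)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineParams":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["matrix"]), np.array(d["translation"]))


def compose_affine(p1: AffineParams, p2: AffineParams) -> AffineParams:
    """Transform equivalent to resampling with p1 and then with p2.

    Resampling is a pull-back, so the composed lookup map is
    w -> M1 (M2 w + t2) + t1.
    """
    return AffineParams(p1.matrix @ p2.matrix,
                        p1.matrix @ p2.translation + p1.translation)


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on the fixed grid."""

    data: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    affine: np.ndarray
    smoothing_fwhm: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError("field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field contains non-finite displacements")


@dataclass
class RegistrationConfig:
    dof: str = "affine"              # "rigid" or "affine"
    pyramid: tuple[int, ...] = (4, 2, 1)
    maxiter: int = 250
    n_restarts: int = 2
    # nonlinear stage
    nl_iterations: int = 120
    nl_step_voxels: float = 0.4
    nl_force_fwhm_mm: float = 6.0
    nl_field_fwhm_mm: float = 1.0
    nl_min_jacobian_fraction: float = 0.99


def correlation_coefficient(a: Volume | np.ndarray, b: Volume | np.ndarray,
                            mask: MaskVolume | np.ndarray | None = None) -> float:
    """Pearson correlation of two images over a mask."""
    x = a.data if isinstance(a, Volume) else np.asarray(a)
    y = b.data if isinstance(b, Volume) else np.asarray(b)
    if x.shape != y.shape:
        raise ValueError("images must share a grid")
    if mask is not None:
        mdat = mask.data if isinstance(mask, MaskVolume) else np.asarray(mask, dtype=bool)
        if not mdat.any():
            raise ValueError("mask is empty")
        x, y = x[mdat], y[mdat]
    x = x.ravel().astype(float)
    y = y.ravel().astype(float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("constant image within mask: correlation undefined")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


_ORDER = {"trilinear": 1, "nearest": 0}


def apply_affine(vol: Volume, p: AffineParams, out_grid: Volume | None = None,
                 interp: str = "trilinear") -> Volume:
    """Resample ``vol`` under the world-space affine onto ``out_grid``.

    The output voxel at world position w takes the value of ``vol`` at
    world position M w + t (pull-back). Out-of-field voxels are 0.
    """
    ref = out_grid if out_grid is not None else vol
    out_shape = ref.data.shape
    # voxel -> voxel map: inv(A_mov) (M A_out i + t)
    A_out = ref.affine
    A_mov_inv = np.linalg.inv(vol.affine)
    M4 = np.eye(4)
    M4[:3, :3] = p.matrix
    M4[:3, 3] = p.translation
    V = A_mov_inv @ M4 @ A_out
    idx = np.indices(out_shape).reshape(3, -1).astype(float)
    coords = V[:3, :3] @ idx + V[:3, 3:4]
    out = ndimage.map_coordinates(vol.data.astype(float), coords,
                                  order=_ORDER[interp], mode="grid-constant", cval=0.0)
    return Volume(out.reshape(out_shape), ref.spacing, A_out.copy(), vol.units)


def _params_to_affine(vec: np.ndarray, center_mm: np.ndarray, dof: str) -> AffineParams:
    t = vec[:3]
    rx, ry, rz = np.radians(vec[3:6])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M = Rz @ Ry @ Rx
    if dof == "affine" and len(vec) >= 12:
        S = np.diag(np.exp(vec[6:9]))
        h = vec[9:12]
        Sh = np.array([[1, h[0], h[1]], [0, 1, h[2]], [0, 0, 1]])
        M = M @ S @ Sh
    # rotate/scale about the fixed-image center
    trans = t + center_mm - M @ center_mm
    return AffineParams(M, trans)


def _subsample(vol: Volume, f: int) -> Volume:
    if f == 1:
        return vol
    sm = gaussian_smooth(vol, tuple(2.0 * s * (f - 1) for s in vol.spacing))
    data = sm.data[::f, ::f, ::f]
    A = vol.affine @ np.diag([f, f, f, 1])
    return Volume(data, tuple(s * f for s in vol.spacing), A, vol.units)


def affine_register(moving: Volume, fixed: Volume,
                    config: RegistrationConfig | None = None) -> AffineParams:
    """Derivative-free CC maximization over rigid or full affine parameters.

    Coarse-to-fine over the configured pyramid; the returned parameters
    never score worse than the identity (falls back with a warning flag
    if the optimizer failed to improve).
    """
    cfg = config or RegistrationConfig()
    n_par = 6 if cfg.dof == "rigid" else 12
    idx = np.indices(fixed.data.shape).reshape(3, -1)
    center_vox = (np.array(fixed.data.shape) - 1) / 2.0
    center_mm = (fixed.affine @ np.append(center_vox, 1.0))[:3]

    vec = np.zeros(n_par)
    for f in cfg.pyramid:
        fx = _subsample(fixed, f)
        mv = _subsample(moving, f)

        def neg_cc(v):
            try:
                p = _params_to_affine(v, center_mm, cfg.dof)
            except ValueError:
                return 1.0
            warped = apply_affine(mv, p, out_grid=fx)
            try:
                return -correlation_coefficient(warped, fx)
            except ValueError:
                return 1.0

        scales = np.concatenate([np.full(3, 2.0 * min(fixed.spacing) * f),
                                 np.full(3, 2.0),
                                 np.full(3, 0.05), np.full(3, 0.05)])[:n_par]
        best_v, best_f = vec, neg_cc(vec)
        for r in range(cfg.n_restarts):
            x0 = best_v if r == 0 else best_v + (r * 0.3) * scales * np.sign(np.sin(np.arange(n_par) + r))
            res = minimize(neg_cc, x0, method="Nelder-Mead",
                           options={"maxiter": cfg.maxiter, "xatol": 1e-3, "fatol": 1e-7,
                                    "initial_simplex": x0 + np.vstack([np.zeros(n_par),
                                                                       np.diag(scales)])})
            if res.fun < best_f:
                best_v, best_f = res.x, res.fun
        vec = best_v

    params = _params_to_affine(vec, center_mm, cfg.dof)
    cc_id = correlation_coefficient(apply_affine(moving, AffineParams.identity(),
                                                 out_grid=fixed), fixed)
    cc_fit = correlation_coefficient(apply_affine(moving, params, out_grid=fixed), fixed)
    if cc_fit < cc_id:
        ident = AffineParams.identity()
        ident.warning = "optimization failed to improve on identity"
        return ident
    return params


def apply_field(vol: Volume, fld: DisplacementField, interp: str = "trilinear") -> Volume:
    """Pull-back resampling: output(x) = vol(world(x) + u(x))."""
    if vol.data.shape != fld.data.shape[:3]:
        raise ValueError("volume and field grids differ")
    A_inv = np.linalg.inv(vol.affine)
    idx = np.indices(vol.data.shape).astype(float)
    world = np.einsum("ij,jxyz->ixyz", vol.affine[:3, :3], idx) + vol.affine[:3, 3][:, None, None, None]
    world = world + np.moveaxis(fld.data, -1, 0)
    coords = np.einsum("ij,jxyz->ixyz", A_inv[:3, :3], world) + A_inv[:3, 3][:, None, None, None]
    out = ndimage.map_coordinates(vol.data.astype(float), coords.reshape(3, -1),
                                  order=_ORDER[interp], mode="grid-constant", cval=0.0)
    return vol.with_data(out.reshape(vol.data.shape))


def _jacobian_positive_fraction(fld: DisplacementField, mask: np.ndarray) -> float:
    u_vox = fld.data / np.array(fld.spacing)
    J = np.zeros(fld.data.shape[:3])
    grads = [[np.gradient(u_vox[..., i], axis=j) for j in range(3)] for i in range(3)]
    F = np.empty(fld.data.shape[:3] + (3, 3))
    for i in range(3):
        for j in range(3):
            F[..., i, j] = grads[i][j] + (1.0 if i == j else 0.0)
    det = np.linalg.det(F)
    return float((det[mask] > 0).mean())


def nonlinear_register(moving: Volume, fixed: Volume,
                       config: RegistrationConfig | None = None,
                       mask: MaskVolume | None = None) -> DisplacementField:
    """Small-deformation fluid registration driven by the gradient of CC.

    Each iteration warps the moving image through the current field,
    computes the analytic gradient of global CC with respect to the warped
    intensities times the spatial image gradient, smooths that force field
    (fluid-like regularization), and takes a step capped at
    ``nl_step_voxels``. Steps that do not increase CC halve the step size.
    Aborts if the field folds (positive-Jacobian fraction drops below the
    configured tolerance).
    """
    cfg = config or RegistrationConfig()
    if moving.data.shape != fixed.data.shape:
        raise ValueError("nonlinear registration expects a shared grid")
    mdat = mask.data.astype(bool) if mask is not None else np.ones(fixed.data.shape, bool)
    spacing = np.array(fixed.spacing)
    fld = DisplacementField(np.zeros(fixed.data.shape + (3,)), fixed.spacing,
                            fixed.affine.copy(), cfg.nl_force_fwhm_mm)

    # standardize within the mask: SSD on standardized images is a strictly
    # decreasing function of CC, so these forces descend the CC objective
    f = fixed.data.astype(float)
    fsd = f[mdat].std()
    if fsd == 0:
        raise ValueError("fixed image constant within mask")
    f_hat = (f - f[mdat].mean()) / fsd
    step = cfg.nl_step_voxels
    cc_prev = correlation_coefficient(moving, fixed, mask)
    helper = Volume(np.zeros_like(f), fixed.spacing, fixed.affine.copy())
    s_min = float(min(spacing))

    for it in range(cfg.nl_iterations):
        warped = apply_field(moving, fld)
        m = warped.data
        msd = m[mdat].std()
        if msd == 0:
            break
        m_hat = (m - m[mdat].mean()) / msd
        diff = (f_hat - m_hat) * mdat
        grads = np.gradient(m_hat, *spacing)
        g2 = sum(g ** 2 for g in grads)
        denom = g2 + diff ** 2 / s_min ** 2
        coef = np.where(denom > 1e-12, diff / np.maximum(denom, 1e-12), 0.0)
        force = np.stack([coef * g for g in grads], axis=-1)  # mm
        for i in range(3):
            force[..., i] = gaussian_smooth(helper.with_data(force[..., i]),
                                            cfg.nl_force_fwhm_mm).data
        fmax = np.abs(force).max()
        if fmax < 1e-12:
            break
        # cap the per-iteration step at a fraction of a voxel
        scale = min(1.0, step * s_min / fmax)
        new_u = fld.data + scale * force
        if cfg.nl_field_fwhm_mm > 0:  # elastic-like regularization of the field
            for i in range(3):
                new_u[..., i] = gaussian_smooth(helper.with_data(new_u[..., i]),
                                                cfg.nl_field_fwhm_mm).data
        trial = DisplacementField(new_u, fld.spacing, fld.affine,
                                  cfg.nl_force_fwhm_mm)
        cc_trial = correlation_coefficient(apply_field(moving, trial), fixed, mask)
        if cc_trial > cc_prev:
            if _jacobian_positive_fraction(trial, mdat) < cfg.nl_min_jacobian_fraction:
                raise RuntimeError(
                    f"displacement field folding at iteration {it}: "
                    f"positive-Jacobian fraction below {cfg.nl_min_jacobian_fraction}")
            fld = trial
            cc_prev = cc_trial
        else:
            step *= 0.5
            if step < 1e-3:
                break
    return fld
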