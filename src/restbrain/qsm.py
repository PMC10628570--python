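"""Quantitative susceptibility mapping: phase unwrapping, background
removal, and dipole inversion.

The chain recovers tissue magnetic susceptibility chi (ppm) from a wrapped
GRE phase volume in three stages:

1. *Laplacian unwrapping.* The Laplacian of the true phase is computed
   from the wrapped phase through the identity
   lap(phi) = cos(phi) lap(sin phi) - sin(phi) lap(cos phi), with all
   Laplacians evaluated spectrally, and the result divided by -4 pi^2 k^2
   in frequency space (the k = 0 coefficient set to 0, so the mean phase
   is fixed to zero: it is not recoverable).
2. *SMV background removal (V-SHARP).* Sphere-mean-value filtering
   phi' = phi - S (x) phi annihilates fields harmonic inside the mask;
   the kernel radius shrinks toward the mask boundary, and the local
   phase attenuated by the filtering is restored by deconvolution with
   K = FT^-1[ FT(S) / (1 - FT(S)) ], truncated where 1 - FT(S) is tiny.
3. *Dipole inversion.* The field-to-susceptibility relation
   phi(k) = field_scale * D(k) chi(k) with the unit dipole kernel
   D(k) = 1/3 - (k . b0)^2 / |k|^2 is inverted by minimizing
   || F^-1(D F(chi)) - phi_nh ||^2 + lambda * R(chi), R the weighted L1
   norm of spatial gradients, via IRLS with LSQR inner solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, lsqr

from .volgrid import MaskVolume, Volume

__all__ = [
    "PhaseVolume",
    "SMVKernels",
    "ChiMap",
    "wrap_phase",
    "laplacian_unwrap",
    "make_smv_kernels",
    "smv_background_remove",
    "dipole_kernel",
    "forward_field",
    "invert_susceptibility",
]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


@dataclass
class PhaseVolume:
    """Phase image in radians, flagged wrapped or unwrapped."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    wrapped: bool = True
    mask: MaskVolume | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("PhaseVolume requires 3D data")
        if self.wrapped:
            lo, hi = self.data.min(), self.data.max()
            if lo <= -np.pi - 1e-9 or hi > np.pi + 1e-9:
                raise ValueError("wrapped phase must lie in (-pi, pi]")


@dataclass
class SMVKernels:
    """Sphere-mean-value kernels at descending radii plus deconvolution setup.

    ``kernels`` maps each radius (mm) to the frequency-space transform of a
    nonnegative spherical kernel normalized to unit sum.
    """

    radii_mm: tuple[float, ...]
    kernels: dict[float, np.ndarray]
    deconv_eps: float = 0.05

    def __post_init__(self) -> None:
        if list(self.radii_mm) != sorted(self.radii_mm, reverse=True):
            raise ValueError("radii must be strictly descending")
        if len(set(self.radii_mm)) != len(self.radii_mm):
            raise ValueError("radii must be strictly descending")


@dataclass
class ChiMap:
    """Susceptibility map in ppm with its inversion provenance."""

    data: np.ndarray
    mask: MaskVolume
    lam: float = 0.0
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    iterations_run: int = 0
    converged: bool = True
    objective_history: list[float] = field(default_factory=list)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        self.data = np.asarray(self.data, dtype=float)


def _k_grids(shape, spacing):
    ks = [np.fft.fftfreq(n, d=s) for n, s in zip(shape, spacing)]
    return np.meshgrid(*ks, indexing="ij")


def _k2(shape, spacing) -> np.ndarray:
    kx, ky, kz = _k_grids(shape, spacing)
    return kx ** 2 + ky ** 2 + kz ** 2


def _spectral_laplacian(f: np.ndarray, k2: np.ndarray) -> np.ndarray:
    return np.real(np.fft.ifftn(-4 * np.pi ** 2 * k2 * np.fft.fftn(f)))


def laplacian_unwrap(phase: PhaseVolume) -> PhaseVolume:
    """Spectral Laplacian phase unwrapping.

    Exact up to an additive harmonic component (constants and slow trends),
    which the downstream background-removal stage absorbs.
    """
    if not phase.wrapped:
        raise ValueError("phase is already unwrapped")
    shape = phase.data.shape
    if min(shape) < 2:
        raise ValueError("degenerate grid for spectral unwrapping")
    k2 = _k2(shape, phase.spacing)
    s, c = np.sin(phase.data), np.cos(phase.data)
    lap = c * _spectral_laplacian(s, k2) - s * _spectral_laplacian(c, k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(k2 > 0, -1.0 / (4 * np.pi ** 2 * k2), 0.0)
    unwrapped = np.real(np.fft.ifftn(inv * np.fft.fftn(lap)))
    return PhaseVolume(unwrapped, phase.spacing, wrapped=False, mask=phase.mask)


def _sphere_kernel_hat(shape, spacing, radius_mm: float) -> np.ndarray:
    """Frequency transform of a normalized spherical indicator kernel."""
    half = [int(np.ceil(radius_mm / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    ker = (gx ** 2 + gy ** 2 + gz ** 2 <= radius_mm ** 2).astype(float)
    ker /= ker.sum()
    big = np.zeros(shape)
    sl = tuple(slice(0, 2 * h + 1) for h in half)
    big[sl] = ker
    # center the kernel at the origin of the periodic grid
    big = np.roll(big, shift=[-h for h in half], axis=(0, 1, 2))
    return np.fft.fftn(big)


def make_smv_kernels(shape, spacing, radii_mm: Sequence[float] | None = None,
                     deconv_eps: float = 0.05) -> SMVKernels:
    """Build the V-SHARP kernel set.

    Default radii span 6 voxels (largest) down to 1 voxel in units of the
    smallest spacing, so the filter can shrink toward the mask edge.
    """
    if radii_mm is None:
        unit = min(spacing)
        radii_mm = [unit * r for r in (6, 5, 4, 3, 2, 1)]
    kernels = {float(r): _sphere_kernel_hat(shape, spacing, float(r)) for r in radii_mm}
    return SMVKernels(tuple(float(r) for r in radii_mm), kernels, deconv_eps)


def smv_background_remove(phase: PhaseVolume, mask: MaskVolume,
                          kernels: SMVKernels | None = None) -> PhaseVolume:
    """Variable-kernel SMV filtering plus deconvolution (V-SHARP).

    Stage 1: phi' = phi - S (x) phi with the largest kernel that fits inside
    the mask at each voxel. Stage 2: deconvolution with the largest kernel,
    phi_nh = phi' + phi' (x) K, zeroing frequencies where |1 - FT(S)| is
    below ``deconv_eps``. The output is restricted to the region eroded by
    the smallest radius.
    """
    if phase.wrapped:
        raise ValueError("phase must be unwrapped before background removal")
    shape = phase.data.shape
    spacing = phase.spacing
    if kernels is None:
        kernels = make_smv_kernels(shape, spacing)

    mdat = mask.data.astype(bool)
    dist = ndimage.distance_transform_edt(mdat, sampling=spacing)
    r_max = float(kernels.radii_mm[0])
    if r_max > dist.max():
        raise ValueError("largest SMV radius exceeds the mask inradius")

    phi = phase.data * mdat
    F_phi = np.fft.fftn(phi)
    F_m = np.fft.fftn(mdat.astype(float))
    hp = np.zeros(shape)
    assigned = np.zeros(shape, dtype=bool)
    for r in kernels.radii_mm:  # descending
        S_hat = kernels.kernels[r]
        # mask-compensated sphere mean: only averages voxels inside the mask
        num = np.real(np.fft.ifftn(S_hat * F_phi))
        den = np.real(np.fft.ifftn(S_hat * F_m))
        mean_r = np.where(den > 1e-6, num / np.maximum(den, 1e-6), 0.0)
        sel = (dist >= r) & ~assigned & mdat
        hp[sel] = phi[sel] - mean_r[sel]
        assigned |= sel

    reliable = assigned
    # stage 2: deconvolution with the largest kernel
    S_hat = kernels.kernels[r_max]
    denom = 1.0 - S_hat
    K_hat = np.where(np.abs(denom) >= kernels.deconv_eps, S_hat / np.where(np.abs(denom) >= kernels.deconv_eps, denom, 1.0), 0.0)
    hp_masked = hp * reliable
    nh = hp_masked + np.real(np.fft.ifftn(K_hat * np.fft.fftn(hp_masked)))
    nh = nh * reliable
    out_mask = MaskVolume(reliable.astype(np.uint8), spacing, mask.affine.copy())
    return PhaseVolume(nh, spacing, wrapped=False, mask=out_mask)


def dipole_kernel(shape, spacing=(1.0, 1.0, 1.0),
                  b0_dir=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Frequency-space unit dipole kernel D(k) = 1/3 - (k.b0)^2/|k|^2, D(0) = 0."""
    b0 = np.asarray(b0_dir, dtype=float)
    nb = np.linalg.norm(b0)
    if nb < 1e-12:
        raise ValueError("b0 direction must be nonzero")
    b0 = b0 / nb
    kx, ky, kz = _k_grids(shape, spacing)
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    kb = kx * b0[0] + ky * b0[1] + kz * b0[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(k2 > 0, 1.0 / 3.0 - kb ** 2 / np.where(k2 > 0, k2, 1.0), 0.0)
    return D


def forward_field(chi: Volume | np.ndarray, b0_dir=(0.0, 0.0, 1.0),
                  field_scale: float = 1.0,
                  spacing: tuple[float, float, float] | None = None) -> PhaseVolume:
    """Field (radians) induced by a susceptibility distribution (ppm)."""
    if isinstance(chi, Volume):
        data, sp = chi.data, chi.spacing
    else:
        data, sp = np.asarray(chi, dtype=float), spacing or (1.0, 1.0, 1.0)
    D = dipole_kernel(data.shape, sp)
    f = field_scale * np.real(np.fft.ifftn(D * np.fft.fftn(data)))
    return PhaseVolume(f, sp, wrapped=False)


def _grad(x: np.ndarray, axis: int) -> np.ndarray:
    return np.roll(x, -1, axis=axis) - x


def _grad_adj(x: np.ndarray, axis: int) -> np.ndarray:
    return np.roll(x, 1, axis=axis) - x


def invert_susceptibility(phase_nh: PhaseVolume, mask: MaskVolume,
                          lam: float = 0.0,
                          weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                          field_scale: float = 1.0,
                          b0_dir=(0.0, 0.0, 1.0),
                          max_outer: int = 5, inner_iter: int = 60,
                          irls_eps: float = 1e-6) -> ChiMap:
    """Regularized dipole inversion by IRLS with LSQR inner solves.

    Minimizes ||M (field_scale F^-1 D F chi - phi_nh)||^2 + lam * R(chi)
    with R the weighted L1 norm of forward-difference gradients, smoothed
    by ``irls_eps`` so each outer iteration is a linear least-squares
    problem solved with LSQR. With lam = 0 a single LSQR solve is run.
    """
    if phase_nh.wrapped:
        raise ValueError("phase must be background-removed (unwrapped) input")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    shape = phase_nh.data.shape
    spacing = phase_nh.spacing
    mdat = mask.data.astype(bool)
    data_mask = phase_nh.mask.data.astype(bool) & mdat if phase_nh.mask is not None else mdat
    D = dipole_kernel(shape, spacing, b0_dir)
    # chi is supported on the mask (susceptibility sources are tissue);
    # solving on the full grid would let the minimal-norm solution park
    # source energy outside the mask and bias tissue chi low.
    nvox = int(mdat.sum())
    b_vec = phase_nh.data[data_mask]

    def A_fwd(x_flat: np.ndarray) -> np.ndarray:
        x = np.zeros(shape)
        x[mdat] = x_flat
        f = field_scale * np.real(np.fft.ifftn(D * np.fft.fftn(x)))
        return f[data_mask]

    def A_adj(y: np.ndarray) -> np.ndarray:
        full = np.zeros(shape)
        full[data_mask] = y
        x = field_scale * np.real(np.fft.ifftn(D * np.fft.fftn(full)))
        return x[mdat]

    def embed(x_flat: np.ndarray) -> np.ndarray:
        x = np.zeros(shape)
        x[mdat] = x_flat
        return x

    def objective(x: np.ndarray) -> float:
        resid = A_fwd(x[mdat]) - b_vec
        obj = float(resid @ resid)
        if lam > 0:
            for ax, w in enumerate(weights):
                g = _grad(x, ax)
                obj += lam * float(np.sum(w * np.sqrt(g ** 2 + irls_eps ** 2)))
        return obj

    nd = int(data_mask.sum())
    nfull = int(np.prod(shape))
    if lam == 0:
        op = LinearOperator((nd, nvox), matvec=A_fwd, rmatvec=A_adj)
        sol = lsqr(op, b_vec, iter_lim=inner_iter, atol=1e-8, btol=1e-8)
        x = embed(sol[0])
        return ChiMap(x, mask, lam, weights, iterations_run=int(sol[2]),
                      converged=True, objective_history=[objective(x)],
                      spacing=spacing)

    x = np.zeros(shape)
    history = [objective(x)]
    converged = False
    for outer in range(max_outer):
        irls_w = []
        for ax, w in enumerate(weights):
            g = _grad(x, ax)
            irls_w.append(np.sqrt(w / np.sqrt(g ** 2 + irls_eps ** 2)))

        def M_fwd(x_flat: np.ndarray) -> np.ndarray:
            xx = embed(x_flat)
            parts = [A_fwd(x_flat)]
            for ax in range(3):
                parts.append(np.sqrt(lam) * (irls_w[ax] * _grad(xx, ax)).ravel())
            return np.concatenate(parts)

        def M_adj(y: np.ndarray) -> np.ndarray:
            out = A_adj(y[:nd])
            off = nd
            for ax in range(3):
                seg = y[off:off + nfull].reshape(shape)
                out = out + np.sqrt(lam) * _grad_adj(irls_w[ax] * seg, ax)[mdat]
                off += nfull
            return out

        rhs = np.concatenate([b_vec, np.zeros(3 * nfull)])
        op = LinearOperator((nd + 3 * nfull, nvox), matvec=M_fwd, rmatvec=M_adj)
        sol = lsqr(op, rhs, iter_lim=inner_iter, atol=1e-8, btol=1e-8)
        x_new = embed(sol[0])
        obj_new = objective(x_new)
        if obj_new > history[-1] + 1e-12:
            # IRLS step failed to decrease the smoothed objective; stop
            break
        x = x_new
        history.append(obj_new)
        if len(history) >= 2 and abs(history[-2] - history[-1]) <= 1e-6 * max(history[-2], 1e-30):
            converged = True
            break
    return ChiMap(x, mask, lam, weights, iterations_run=len(history) - 1,
                  converged=converged or len(history) - 1 == max_outer,
                  objective_history=history, spacing=spacing)
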