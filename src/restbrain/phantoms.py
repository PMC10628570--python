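"""Seeded phantom generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and an integer seed,
returns a :class:`PhantomBundle` carrying both the simulated images and
the exact ground truth used to build them, and emulates the acquisition
geometry of a 3 T resting-state protocol: 64x64 matrix with 33 slices and
210 time points for BOLD (6,930 two-dimensional slice images per run),
and 35 slices with 25 diffusion directions at b = 1,000 s/mm^2 plus two
b = 0 volumes for DWI (1,820 slice images at 52 volumes). Forward models
used here (dipole field, tensor signal equation) are the same operators
the reconstruction modules invert, enabling closed-loop recovery tests.

No attempt is made at realistic anatomy: brains are ellipsoids, activity
blobs are spheres, and noise is Gaussian (optionally Rician for DWI).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .dti import GradientScheme, write_scheme
from .volgrid import BoldSeries, MaskVolume, Volume, gaussian_smooth, write_volume

__all__ = [
    "PhantomBundle",
    "make_structural_phantom",
    "make_bold_phantom",
    "make_dwi_phantom",
    "make_susceptibility_phantom",
    "make_group_maps",
    "default_dwi_scheme",
    "default_tensor_field",
    "save_bundle",
]

# BOLD acquisition geometry: FOV 24 cm / 64 matrix -> 3.75 mm in plane,
# 4 mm slices, TR 2 s, 33 slices x 210 time points.
BOLD_SHAPE = (64, 64, 33)
BOLD_SPACING = (3.75, 3.75, 4.0)
BOLD_TR = 2.0
BOLD_N_T = 210

# DWI geometry: 128 matrix over 24 cm FOV, 35 slices of 4 mm,
# b = 0/1000 s/mm^2, 25 directions.
DWI_SHAPE = (128, 128, 35)
DWI_SPACING = (1.875, 1.875, 4.0)
DWI_N_DIRECTIONS = 25
DWI_BVALUE = 1000.0
DWI_N_B0 = 2
DWI_N_AVERAGES = 2  # 25 * 2 + 2 = 52 volumes -> 35 * 52 = 1,820 slice images


@dataclass
class PhantomBundle:
    """Generated images plus the ground truth they were built from."""

    volumes: dict[str, Any]
    truth: dict[str, Any]
    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def n_slice_images(self, key: str) -> int:
        """Number of 2D slice images in a (4D) volume: n_slices * n_volumes."""
        arr = self.volumes[key].data
        if arr.ndim == 3:
            return arr.shape[2]
        return arr.shape[2] * arr.shape[3]


def _ellipsoid_rho(shape, spacing, center_mm, semiaxes_mm):
    """Normalized ellipsoid radius field: rho <= 1 inside."""
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semiaxes_mm))
    return np.sqrt(rho2)


def make_structural_phantom(shape=BOLD_SHAPE, spacing=BOLD_SPACING,
                            noise_sd: float = 0.0, seed: int = 0) -> PhantomBundle:
    """Ellipsoidal bright brain, dark CSF gap, bright skull shell, plus noise.

    Intensities: brain 1.0, CSF 0.05, skull/scalp shell 0.8, background 0.
    The truth mask is the exact discretized brain ellipsoid. Contrast
    (brain minus background) is 1, so CNR = 1 / noise_sd.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if shape[0] < 32 or shape[1] < 32:
        raise ValueError("in-plane shape must be >= 32")
    rng = np.random.default_rng(seed)
    fov = [n * s for n, s in zip(shape, spacing)]
    center = [f / 2 for f in fov]
    semi = [0.32 * fov[0], 0.36 * fov[1], 0.38 * fov[2]]
    rho = _ellipsoid_rho(shape, spacing, center, semi)

    img = np.zeros(shape, dtype=float)
    mask = rho <= 1.0
    # CSF gap and skull/scalp shell surround the brain laterally, only on
    # slices that contain brain (an imaged slab, not a closed shell: a
    # filled bright cap beyond the poles would not be brain-like)
    has_brain = mask.any(axis=(0, 1))
    img[(rho > 1.0) & (rho <= 1.12) & has_brain[None, None, :]] = 0.05
    img[(rho > 1.12) & (rho <= 1.28) & has_brain[None, None, :]] = 0.8
    img[mask] = 1.0
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)

    vol = Volume(img, spacing)
    return PhantomBundle(
        volumes={"structural": vol},
        truth={"brain_mask": MaskVolume(mask.astype(np.uint8), spacing, vol.affine.copy())},
        seed=seed,
        params={"shape": tuple(shape), "spacing": tuple(spacing), "noise_sd": noise_sd},
    )


def _low_freq_signal(n_t: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth slow signal: sum of sinusoids within the 0.01-0.08 Hz band."""
    t = np.arange(n_t) * tr
    freqs = rng.uniform(0.01, 0.08, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    sig = np.sum([np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases)], axis=0)
    return sig / sig.std()


def make_bold_phantom(shape_xyz=BOLD_SHAPE, n_t: int = BOLD_N_T,
                      blob_spec: list[tuple[tuple[int, int, int], float, float]] | None = None,
                      ar1: float = 0.3, seed: int = 0,
                      spacing=BOLD_SPACING, tr: float = BOLD_TR) -> PhantomBundle:
    """4D BOLD series: AR(1) voxel noise plus a shared slow signal in blobs.

    blob_spec is a list of (center_voxel, radius_voxels, shared_fraction f);
    inside a blob each voxel's series is (1 - f) * own_noise + f * shared.
    Truth lists one boolean mask per blob.
    """
    if n_t < 10:
        raise ValueError("n_t must be >= 10")
    if not (0 <= ar1 < 1):
        raise ValueError("ar1 must be in [0, 1)")
    if blob_spec is None:
        nx, ny, nz = shape_xyz
        blob_spec = [((int(0.35 * nx), int(0.35 * ny), nz // 2), max(2.0, 0.06 * nx), 0.8),
                     ((int(0.65 * nx), int(0.62 * ny), nz // 2), max(2.0, 0.06 * nx), 0.8)]
    rng = np.random.default_rng(seed)

    # AR(1) noise with unit marginal variance
    innov_sd = np.sqrt(1.0 - ar1 ** 2)
    noise = np.empty(shape_xyz + (n_t,), dtype=np.float32)
    noise[..., 0] = rng.standard_normal(shape_xyz)
    for t in range(1, n_t):
        noise[..., t] = ar1 * noise[..., t - 1] + innov_sd * rng.standard_normal(shape_xyz).astype(np.float32)

    data = noise.copy()
    idx = np.indices(shape_xyz)
    blob_masks = []
    for center, radius, frac in blob_spec:
        if not (0 <= frac <= 1):
            raise ValueError("shared-signal fraction must be in [0, 1]")
        if any(c < 0 or c >= n for c, n in zip(center, shape_xyz)):
            raise ValueError(f"blob center {center} outside grid {shape_xyz}")
        d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
        bmask = d2 <= radius ** 2
        blob_masks.append(bmask)
        shared = _low_freq_signal(n_t, tr, rng).astype(np.float32)
        data[bmask] = (1.0 - frac) * noise[bmask] + frac * shared[None, :]

    data = data + 100.0  # baseline intensity
    series = BoldSeries(data, spacing, tr_seconds=tr)
    return PhantomBundle(
        volumes={"bold": series},
        truth={"blob_masks": blob_masks,
               "n_slice_images": shape_xyz[2] * n_t},
        seed=seed,
        params={"shape": tuple(shape_xyz), "n_t": n_t, "ar1": ar1,
                "blob_spec": blob_spec, "tr": tr},
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the hemisphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - i / n)  # polar angle over upper hemisphere
    theta = np.pi * (1 + 5 ** 0.5) * i
    dirs = np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def default_dwi_scheme(n_directions: int = DWI_N_DIRECTIONS, bvalue: float = DWI_BVALUE,
                       n_b0: int = DWI_N_B0, n_averages: int = DWI_N_AVERAGES) -> GradientScheme:
    """Gradient table for the default protocol: 25 directions x 2 + 2 b0 = 52 volumes."""
    dirs = _fibonacci_directions(n_directions)
    bvecs = np.vstack([np.zeros((n_b0, 3))] + [dirs] * n_averages)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions * n_averages, bvalue)])
    return GradientScheme(bvals, bvecs)


def default_tensor_field(shape=(16, 16, 8)) -> np.ndarray:
    """Simple truth field: isotropic background with an anisotropic core.

    Background D = 0.7e-3 * I mm^2/s (grey-matter-like); a central block is
    stick-like diag(1.7, 0.3, 0.2)e-3 (white-matter-like).
    """
    tensors = np.zeros(shape + (3, 3), dtype=float)
    tensors[..., 0, 0] = tensors[..., 1, 1] = tensors[..., 2, 2] = 0.7e-3
    cx, cy, cz = (s // 2 for s in shape)
    hx, hy, hz = (max(1, s // 4) for s in shape)
    core = np.diag([1.7e-3, 0.3e-3, 0.2e-3])
    tensors[cx - hx:cx + hx, cy - hy:cy + hy, cz - hz:cz + hz] = core
    return tensors


def make_dwi_phantom(tensor_field: np.ndarray | None = None,
                     scheme: GradientScheme | None = None,
                     snr: float = np.inf, seed: int = 0,
                     s0: float = 1000.0,
                     n_slices: int = DWI_SHAPE[2],
                     spacing=DWI_SPACING) -> PhantomBundle:
    """DWI signals S = S0 exp(-b g^T D g), optional Rician noise at given SNR.

    With the default scheme and 35 slices this produces 52 volumes, i.e.
    35 x 52 = 1,820 two-dimensional slice images.
    """
    if scheme is None:
        scheme = default_dwi_scheme()
    if tensor_field is None:
        tensor_field = default_tensor_field(shape=(16, 16, n_slices))
    tensor_field = np.asarray(tensor_field, dtype=float)
    if tensor_field.shape[-2:] != (3, 3):
        raise ValueError("tensor_field must have trailing (3, 3) matrices")
    if not np.allclose(tensor_field, np.swapaxes(tensor_field, -1, -2)):
        raise ValueError("tensors must be symmetric")
    evals = np.linalg.eigvalsh(tensor_field)
    if np.any(evals < -1e-12):
        raise ValueError("tensors must be positive semidefinite")

    rng = np.random.default_rng(seed)
    shape = tensor_field.shape[:3]
    b = scheme.bvals
    g = scheme.bvecs
    # exponent: -b * g^T D g per voxel and volume
    quad = np.einsum("vi,...ij,vj->...v", g, tensor_field, g)
    signal = s0 * np.exp(-b[None, None, None, :] * quad)
    if np.isfinite(snr):
        sigma = s0 / snr
        re = signal + rng.normal(0, sigma, signal.shape)
        im = rng.normal(0, sigma, signal.shape)
        signal = np.sqrt(re ** 2 + im ** 2)  # Rician magnitude

    series = BoldSeries(signal, spacing, tr_seconds=8.5)
    return PhantomBundle(
        volumes={"dwi": series},
        truth={"tensor_field": tensor_field, "s0": s0,
               "n_slice_images": shape[2] * scheme.n_volumes},
        seed=seed,
        params={"snr": snr, "n_volumes": scheme.n_volumes, "scheme": scheme},
    )


def make_susceptibility_phantom(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0),
                                spheres: list[tuple[tuple[float, float, float], float, float]] | None = None,
                                background_sources: list[tuple[tuple[float, float, float], float, float]] | None = None,
                                field_scale: float = 16.0,
                                noise_sd_rad: float = 0.0,
                                seed: int = 0) -> PhantomBundle:
    """Sphere susceptibility phantom with wrapped-phase output.

    spheres: (center_voxel, radius_voxels, chi_ppm) inside the brain mask;
    background_sources: same format, outside the mask, contributing a field
    that is harmonic within the mask. field_scale converts ppm to radians
    (gamma * B0 * TE * 1e-6; 16 rad/ppm ~ 3 T at TE = 20 ms). The wrapped
    phase is wrap(field_scale * dipole_field(chi) + background + noise).
    """
    from .qsm import dipole_kernel, wrap_phase

    if spheres is None:
        n = min(shape)
        spheres = [((0.38 * shape[0], 0.5 * shape[1], 0.5 * shape[2]), 0.09 * n, 0.10),
                   ((0.64 * shape[0], 0.5 * shape[1], 0.5 * shape[2]), 0.08 * n, 0.05)]
    if background_sources is None:
        background_sources = [((32.0, 32.0, float(shape[2] + 14)), 10.0, 4.0)]
    rng = np.random.default_rng(seed)

    idx = np.indices(shape).astype(float)
    center = [(n - 1) / 2 for n in shape]
    r_mask = 0.42 * min(shape)
    dist_c = np.sqrt(sum((idx[i] - center[i]) ** 2 for i in range(3)))
    mask = dist_c <= r_mask

    chi = np.zeros(shape, dtype=float)
    claimed = np.zeros(shape, dtype=bool)
    for c, r, val in spheres:
        d2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
        sph = d2 <= r ** 2
        if np.any(sph & ~mask):
            raise ValueError(f"sphere at {c} extends outside the brain mask")
        if np.any(sph & claimed):
            raise ValueError(f"sphere at {c} overlaps a previous sphere")
        claimed |= sph
        chi[sph] = val

    # Background susceptibility on a padded grid so external sources produce
    # a field that is harmonic inside the (source-free) mask.
    pad = max(16, shape[2] // 2 + 16)
    big_shape = tuple(n + 2 * pad for n in shape)
    chi_bg = np.zeros(big_shape, dtype=float)
    bigidx = np.indices(big_shape).astype(float)
    for c, r, val in background_sources:
        cc = [ci + pad for ci in c]
        d2 = sum((bigidx[i] - cc[i]) ** 2 for i in range(3))
        sph = d2 <= r ** 2
        inside = sph[pad:pad + shape[0], pad:pad + shape[1], pad:pad + shape[2]]
        if np.any(inside & mask):
            raise ValueError(f"background source at {c} intersects the brain mask")
        chi_bg[sph] = val

    D = dipole_kernel(shape, spacing)
    local_rad = field_scale * np.real(np.fft.ifftn(D * np.fft.fftn(chi)))

    Dbig = dipole_kernel(big_shape, spacing)
    bg_big = field_scale * np.real(np.fft.ifftn(Dbig * np.fft.fftn(chi_bg)))
    bg_rad = bg_big[pad:pad + shape[0], pad:pad + shape[1], pad:pad + shape[2]]

    total = local_rad + bg_rad
    if noise_sd_rad > 0:
        total = total + rng.normal(0, noise_sd_rad, shape)
    wrapped = wrap_phase(total)

    mask_vol = MaskVolume(mask.astype(np.uint8), spacing)
    return PhantomBundle(
        volumes={"wrapped_phase": Volume(wrapped, spacing, units="rad"),
                 "true_phase": Volume(total, spacing, units="rad")},
        truth={"chi": Volume(chi, spacing, units="ppm"),
               "mask": mask_vol,
               "background_rad": Volume(bg_rad, spacing, units="rad"),
               "local_rad": Volume(local_rad, spacing, units="rad"),
               "field_scale": field_scale},
        seed=seed,
        params={"shape": tuple(shape), "spheres": spheres,
                "field_scale": field_scale, "noise_sd_rad": noise_sd_rad},
    )


def make_group_maps(n_a: int = 100, n_b: int = 20,
                    effect_blobs: list[tuple[tuple[int, int, int], float, float]] | None = None,
                    smoothness_fwhm: float = 6.0, seed: int = 0,
                    shape=BOLD_SHAPE, spacing=BOLD_SPACING) -> PhantomBundle:
    """Two stacks of smooth unit-variance Gaussian maps with optional effects.

    Cohort sizes default to the study design of 100 patients vs 20 controls.
    effect_blobs is a list of (center_voxel, radius_voxels, cohens_d); group A
    means are shifted by d (maps are standardized to unit variance) inside
    each blob. An ellipsoidal analysis mask is included in the truth.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)

    fov = [n * s for n, s in zip(shape, spacing)]
    rho = _ellipsoid_rho(shape, spacing, [f / 2 for f in fov],
                         [0.4 * f for f in fov])
    mask = rho <= 1.0

    idx = np.indices(shape)
    blob_masks, ds = [], []
    if effect_blobs:
        for center, radius, d in effect_blobs:
            d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
            bmask = d2 <= radius ** 2
            if np.any(bmask & ~mask):
                raise ValueError(f"effect blob at {center} leaves the analysis mask")
            blob_masks.append(bmask)
            ds.append(d)

    def _stack(n_subj: int, shifted: bool) -> np.ndarray:
        maps = np.empty(shape + (n_subj,), dtype=np.float32)
        base = Volume(np.zeros(shape), spacing)
        for s in range(n_subj):
            m = gaussian_smooth(base.with_data(rng.standard_normal(shape)),
                                smoothness_fwhm).data
            m = m / m[mask].std()
            if shifted:
                for bmask, d in zip(blob_masks, ds):
                    m[bmask] += d
            maps[..., s] = m
        return maps

    stack_a = _stack(n_a, shifted=True)
    stack_b = _stack(n_b, shifted=False)
    return PhantomBundle(
        volumes={"group_a": stack_a, "group_b": stack_b},
        truth={"mask": MaskVolume(mask.astype(np.uint8), spacing),
               "blob_masks": blob_masks, "cohens_d": ds},
        seed=seed,
        params={"n_a": n_a, "n_b": n_b, "smoothness_fwhm": smoothness_fwhm,
                "shape": tuple(shape)},
    )


def save_bundle(bundle: PhantomBundle, outdir: str | Path) -> dict[str, str]:
    """Write bundle volumes as NIfTI (+ bvec/bval for DWI) with a JSON sidecar.

    Returns a manifest mapping logical names to written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, obj in bundle.volumes.items():
        if isinstance(obj, (Volume, BoldSeries, MaskVolume)):
            p = outdir / f"{name}.nii.gz"
            write_volume(obj, p)
            manifest[name] = str(p)
    for name, obj in bundle.truth.items():
        if isinstance(obj, (Volume, MaskVolume)):
            p = outdir / f"truth_{name}.nii.gz"
            write_volume(obj, p)
            manifest[f"truth_{name}"] = str(p)
    scheme = bundle.params.get("scheme")
    if isinstance(scheme, GradientScheme):
        write_scheme(scheme, outdir / "dwi.bvec", outdir / "dwi.bval")
        manifest["bvec"] = str(outdir / "dwi.bvec")
        manifest["bval"] = str(outdir / "dwi.bval")
    sidecar = {"seed": bundle.seed,
               "params": {k: v for k, v in bundle.params.items()
                          if isinstance(v, (int, float, str, list, tuple, bool, type(None)))}}
    (outdir / "bundle.json").write_text(json.dumps(sidecar, default=str, indent=2))
    manifest["sidecar"] = str(outdir / "bundle.json")
    return manifest
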