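"""Deformable-contour brain extraction (BET-style), slice by slice.

A closed polygon of N vertices is initialized as a circle inside the brain
on each axial slice and evolved under three forces until it settles on the
brain boundary:

* u1, the *tension* force: the tangential component of the vector s from a
  vertex to the midpoint of its two neighbors, which keeps the vertices
  evenly spaced.
* u2, the *smoothing* force: the normal component s_n of s scaled by a
  bounded smooth step of the local curvature radius r = l^2 / (2 |s_n|)
  (l the mean neighbor distance), so sharp bends are pulled in strongly
  and gentle bends barely at all. The step uses the curvature bounds
  r_min, r_max through E = (1/r_min + 1/r_max)/2 and
  F = 6 / (1/r_min + 1/r_max).
* u3, the *expansion* force along the surface normal, with magnitude
  2 (I_min - t1) / (I_max - t2): I_min and I_max are the extreme
  intensities found by searching inward from the vertex over distances d1
  and d2, t2 is the global background threshold, and t1 = t2 +
  b_t (I_max - t2) is the locally adaptive threshold. The force pushes
  outward while the local minimum stays above t1 (still inside bright
  tissue) and reverses once the vertex overshoots into dark background,
  so the resultant of the three forces approaches zero at the tissue edge.

The evolved polygons are rasterized slice-wise into a 3D binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

from .volgrid import MaskVolume, Volume

__all__ = [
    "BETParams",
    "ContourState",
    "initialize_contour",
    "contour_forces",
    "evolve_contour",
    "extract_brain",
]


@dataclass
class BETParams:
    """Contour-evolution parameters.

    Distances are in mm and converted to pixels with the in-plane spacing.
    t2 is the background/image threshold as a fraction of the robust
    (2nd-98th percentile) intensity range; bt in (0, 1) balances the local
    threshold between background and local maximum.
    """

    n_points: int = 64
    shrink_m: float = 2.0
    t2: float = 0.02
    bt: float = 0.5
    d1_mm: float = 7.0
    d2_mm: float = 14.0
    rmin_mm: float = 3.33
    rmax_mm: float = 10.0
    max_iter: int = 500
    tol: float = 0.01
    damping: float = 0.5

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if not (0 < self.bt < 1):
            raise ValueError("bt must be in (0, 1)")
        if self.d1_mm > self.d2_mm:
            raise ValueError("d1 must be <= d2")
        if self.rmin_mm >= self.rmax_mm:
            raise ValueError("rmin must be < rmax")


@dataclass
class ContourState:
    """Ordered closed polygon (pixel coordinates, (row, col)) on one slice."""

    points: np.ndarray  # (N, 2)
    center: np.ndarray  # (2,)
    iteration: int = 0
    force_history: list[float] = field(default_factory=list)


def _robust_thresholds(img: np.ndarray, params: BETParams) -> tuple[float, float]:
    """(t2_abs, robust range) from the 2nd-98th percentile intensity range."""
    p2, p98 = np.percentile(img, [2, 98])
    rng = max(p98 - p2, 1e-12)
    return p2 + params.t2 * rng, rng


def initialize_contour(slice_img: np.ndarray, params: BETParams,
                       thresholds: tuple[float, float] | None = None) -> ContourState:
    """Circle of radius r0/m about the intensity centroid of the foreground.

    r0 is the equivalent radius of the above-threshold area; N vertices are
    placed at equal angles. ``thresholds`` lets a volume-level caller supply
    the global (t2_abs, robust range) instead of per-slice estimates.
    """
    img = np.asarray(slice_img, dtype=float)
    t2_abs, _ = thresholds if thresholds is not None else _robust_thresholds(img, params)
    fg = img > t2_abs
    if not fg.any():
        raise ValueError("slice has no above-threshold foreground")
    # the initial circle must start inside brain tissue: suppress thin bright
    # structures (skull/scalp shells) by keeping the largest connected
    # component of the eroded foreground, restored by dilation
    from scipy import ndimage as _ndi
    eroded = _ndi.binary_erosion(fg, iterations=2)
    if eroded.any():
        labels, n_lab = _ndi.label(eroded)
        largest = labels == (np.bincount(labels.ravel())[1:].argmax() + 1)
        fg = _ndi.binary_dilation(largest, iterations=2) & fg
    w = np.where(fg, img, 0.0)
    total = w.sum()
    rows, cols = np.indices(img.shape)
    center = np.array([float((rows * w).sum() / total), float((cols * w).sum() / total)])
    r0 = np.sqrt(fg.sum() / np.pi)
    radius = r0 / params.shrink_m
    ang = 2 * np.pi * np.arange(params.n_points) / params.n_points
    pts = np.column_stack([center[0] + radius * np.cos(ang),
                           center[1] + radius * np.sin(ang)])
    return ContourState(points=pts, center=center)


def _bilinear(img: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Sample img at float (row, col) positions, clamped to the frame."""
    r = np.clip(pts[:, 0], 0, img.shape[0] - 1)
    c = np.clip(pts[:, 1], 0, img.shape[1] - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, img.shape[0] - 1)
    c1 = np.minimum(c0 + 1, img.shape[1] - 1)
    fr, fc = r - r0, c - c0
    return (img[r0, c0] * (1 - fr) * (1 - fc) + img[r1, c0] * fr * (1 - fc)
            + img[r0, c1] * (1 - fr) * fc + img[r1, c1] * fr * fc)


def contour_forces(state: ContourState, slice_img: np.ndarray,
                   params: BETParams,
                   spacing_mm: tuple[float, float] = (1.0, 1.0),
                   thresholds: tuple[float, float] | None = None,
                   return_components: bool = False):
    """Per-vertex displacement u1 + u2 + u3 (pixel units).

    With ``return_components`` the three forces are returned separately
    as a (u1, u2, u3) tuple.
    """
    img = np.asarray(slice_img, dtype=float)
    pts = state.points
    n = len(pts)
    prev_pts = np.roll(pts, 1, axis=0)
    next_pts = np.roll(pts, -1, axis=0)
    if np.any(np.all(np.isclose(prev_pts, next_pts), axis=1)):
        raise ValueError("degenerate neighbor pair: A1 == A2")

    px = float(np.mean(spacing_mm))  # mm per pixel (in-plane assumed ~isotropic)
    ac = 0.5 * (prev_pts + next_pts)
    s = ac - pts
    chord = next_pts - prev_pts
    chord_len = np.linalg.norm(chord, axis=1, keepdims=True)
    t_hat = chord / np.maximum(chord_len, 1e-12)
    s_t = (np.sum(s * t_hat, axis=1, keepdims=True)) * t_hat
    s_n = s - s_t
    sn_norm = np.linalg.norm(s_n, axis=1)

    u1 = s_t

    # smoothing: bounded smooth step of local curvature 1/r
    l = 0.5 * (np.linalg.norm(pts - prev_pts, axis=1)
               + np.linalg.norm(pts - next_pts, axis=1))
    rmin_px = params.rmin_mm / px
    rmax_px = params.rmax_mm / px
    E = 0.5 * (1.0 / rmin_px + 1.0 / rmax_px)
    F = 6.0 / (1.0 / rmin_px + 1.0 / rmax_px)
    with np.errstate(divide="ignore"):
        inv_r = np.where(sn_norm > 1e-12, 2.0 * sn_norm / np.maximum(l, 1e-12) ** 2, 0.0)
    f2 = 0.5 * (1.0 + np.tanh(F * (inv_r - E)))
    u2 = s_n * f2[:, None]

    # expansion along the inward normal, driven by intensities found inward
    area2 = np.sum(pts[:, 0] * (np.roll(pts[:, 1], -1) - np.roll(pts[:, 1], 1)))
    # inward = toward the polygon interior, found from the signed area orientation
    normal = np.column_stack([t_hat[:, 1], -t_hat[:, 0]])
    inward = normal if area2 > 0 else -normal
    inward_to_center = np.sum((state.center - pts) * inward, axis=1)
    inward = np.where(np.median(inward_to_center) >= 0, 1.0, -1.0) * inward

    t2_abs, _ = thresholds if thresholds is not None else _robust_thresholds(img, params)
    d1_px = max(1, int(round(params.d1_mm / px)))
    d2_px = max(1, int(round(params.d2_mm / px)))
    steps2 = np.arange(d2_px + 1)
    samples = np.stack([_bilinear(img, pts + inward * j) for j in steps2], axis=1)
    i_min = samples[:, :d1_px + 1].min(axis=1)
    i_max = samples.max(axis=1)
    t1 = t2_abs + params.bt * (i_max - t2_abs)
    denom = np.maximum(i_max - t2_abs, 1e-12)
    f3 = 2.0 * (i_min - t1) / denom
    u3 = -inward * f3[:, None]  # positive f3 pushes outward

    if return_components:
        return u1, u2, u3
    return u1 + u2 + u3


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def evolve_contour(state: ContourState, slice_img: np.ndarray, params: BETParams,
                   spacing_mm: tuple[float, float] = (1.0, 1.0),
                   thresholds: tuple[float, float] | None = None) -> ContourState:
    """Iterate damped synchronous vertex updates until displacements settle."""
    img = np.asarray(slice_img, dtype=float)
    pts = state.points.copy()
    history: list[float] = []
    it = 0
    for it in range(1, params.max_iter + 1):
        cur = ContourState(pts, state.center, it)
        forces = contour_forces(cur, img, params, spacing_mm, thresholds)
        disp = params.damping * forces
        pts = pts + disp
        history.append(float(np.mean(np.linalg.norm(forces, axis=1))))
        if _polygon_area(pts) < 3.0:
            raise RuntimeError("contour collapsed (area < 3 px^2): bad parameters")
        if np.max(np.linalg.norm(disp, axis=1)) < params.tol:
            break
    return ContourState(pts, state.center, it, history)


def extract_brain(vol: Volume, params: BETParams | None = None) -> MaskVolume:
    """Slice-wise contour evolution rasterized into a 3D brain mask."""
    params = params or BETParams()
    data = np.asarray(vol.data, dtype=float)
    if data.ndim != 3:
        raise ValueError("extract_brain expects a 3D structural volume")
    mask = np.zeros(data.shape, dtype=np.uint8)
    # volume-level robust thresholds so noise-only slices stay empty
    t2_abs, rng = _robust_thresholds(data, params)
    thresholds = (t2_abs, rng)
    in_plane = (vol.spacing[0], vol.spacing[1])
    rows, cols = np.indices(data.shape[:2])
    for z in range(data.shape[2]):
        sl = data[:, :, z]
        if (sl > t2_abs).sum() < 9:  # nothing brain-sized on this slice
            continue
        try:
            st = initialize_contour(sl, params, thresholds)
        except ValueError:
            continue
        # the model starts inside brain tissue: skip slices whose initial
        # disk is not bright (skull/scalp rings, pure noise beyond the poles)
        radius = np.linalg.norm(st.points[0] - st.center)
        disk = (rows - st.center[0]) ** 2 + (cols - st.center[1]) ** 2 <= radius ** 2
        if not disk.any() or np.median(sl[disk]) < t2_abs + 0.25 * rng:
            continue
        try:
            st = evolve_contour(st, sl, params, in_plane, thresholds)
        except (ValueError, RuntimeError):
            continue
        mask[:, :, z] = polygon2mask(sl.shape, st.points).astype(np.uint8)
    return MaskVolume(mask, vol.spacing, vol.affine.copy())
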