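"""Group-average 3-D eye templates by iterated rigid align-and-average.

The procedure mirrors atlas construction for binary shapes:

1. centroid-centre every mask and average voxel-wise -> blurry initial
   template (a probability volume);
2. rigidly align each mask (rotation + translation, *no scaling* — size
   differences between groups are the signal) to the blurry template and
   re-average -> refined global template;
3. align each group's masks to the refined template and average within the
   group;
4. Gaussian-smooth and threshold at 0.5 -> the final smooth group mask.

Left and right eyes are processed independently by the caller.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .morphometry import EyeMask, _CONN26

__all__ = [
    "EyeTemplate",
    "RigidTransform",
    "voxelwise_average",
    "rigid_align",
    "resample_mask",
    "build_group_template",
    "export_surface",
]


@dataclass
class RigidTransform:
    """6-DOF transform p' = R @ (p - centroid) + translation (world mm).

    ``centroid`` is the moving mask's foreground centroid, so the rotation
    pivots about the shape itself; translation is expressed in the centred
    template frame (template grid centre = world origin).
    """

    rotation: np.ndarray          # 3x3
    translation: np.ndarray       # (3,) mm
    centroid: np.ndarray          # (3,) mm, pivot in the moving mask's frame
    metric: float                 # mean template probability achieved
    metric_init: float
    improved: bool                # False -> optimizer returned initialization

    @property
    def euler_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler("xyz", degrees=True)


@dataclass
class EyeTemplate:
    """Probabilistic average eye plus its thresholded smooth mask."""

    probability_volume: np.ndarray
    final_mask: np.ndarray
    voxel_size: tuple
    group_label: str | None = None
    eye_side: str | None = None
    n_contributing: int = 0

    def to_mask(self) -> EyeMask:
        return EyeMask(self.final_mask, voxel_size=self.voxel_size,
                       eye_side=self.eye_side or "right")


def _digest(mask: EyeMask) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(mask.data).tobytes())
    h.update(np.asarray(mask.spacing).tobytes())
    return h.hexdigest()


def _canonical_order(masks):
    # content-digest ordering makes every averaging step independent of the
    # order the caller supplies the masks in (bitwise reproducibility)
    return sorted(masks, key=_digest)


def _common_shape(masks, pad: int = 6) -> tuple:
    shapes = np.array([m.data.shape for m in masks])
    return tuple(int(s) for s in shapes.max(axis=0) + 2 * pad)


def _check_common_spacing(masks) -> np.ndarray:
    sp = np.array([m.spacing for m in masks])
    if not np.allclose(sp, sp[0], atol=1e-9):
        raise ValueError("masks must share a common voxel size")
    return sp[0]


def voxelwise_average(masks, shape: tuple | None = None) -> np.ndarray:
    """Per-voxel mean of binary masks after centroid-centring each one.

    Each mask is translated (integer shift, so values stay binary) so its
    foreground centroid sits at the centre of a common grid; the returned
    probability volume lives on that grid with the world origin at its
    centre.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("no masks")
    spacing = _check_common_spacing(masks)
    if shape is None:
        shape = _common_shape(masks)
    center = (np.array(shape) - 1) / 2.0
    acc = np.zeros(shape, dtype=np.float64)
    for m in masks:
        idx = np.argwhere(m.data)
        shift = np.round(center - idx.mean(axis=0)).astype(int)
        new = idx + shift
        if new.min() < 0 or np.any(new >= np.array(shape)):
            raise ValueError("no masks fit: common grid too small")
        acc[new[:, 0], new[:, 1], new[:, 2]] += 1.0
    return acc / len(masks)


def _template_interp(template: np.ndarray, spacing, pts_mm: np.ndarray) -> np.ndarray:
    center = (np.array(template.shape) - 1) / 2.0
    idx = pts_mm / spacing + center
    return ndimage.map_coordinates(template, idx.T, order=1,
                                   mode="constant", cval=0.0)


def _principal_axes(points: np.ndarray, weights=None) -> np.ndarray:
    if weights is None:
        weights = np.ones(len(points))
    mu = np.average(points, axis=0, weights=weights)
    d = points - mu
    cov = (d * weights[:, None]).T @ d / weights.sum()
    _, vec = np.linalg.eigh(cov)
    return vec   # columns: ascending eigenvalue order


def rigid_align(mask: EyeMask, template: np.ndarray,
                spacing=None, smooth_sigma_vox: float = 1.0) -> RigidTransform:
    """Rigid (rotation + translation) alignment of a mask onto a template.

    The similarity metric is the mean template probability sampled at the
    transformed foreground voxel centres (for binary volumes this is the
    overlap fraction); the template is lightly smoothed so the metric has a
    usable gradient.  Initialisation: centroid match plus a principal-axes
    rotation (best of the four proper sign assignments); refinement by
    Powell search over the 6 parameters.  If refinement fails to improve on
    the initialisation, the initialisation is returned with
    ``improved=False``.
    """
    if spacing is None:
        spacing = mask.spacing
    spacing = np.asarray(spacing, dtype=float)
    if template.max() <= 0:
        raise ValueError("degenerate template")
    smoothed = ndimage.gaussian_filter(template, smooth_sigma_vox)

    idx = np.argwhere(mask.data)
    centroid_mm = mask.world(idx.mean(axis=0))
    pts = mask.world(idx) - centroid_mm

    def metric(params):
        R = Rotation.from_euler("xyz", params[:3], degrees=True).as_matrix()
        moved = pts @ R.T + params[3:]
        return -float(np.mean(_template_interp(smoothed, spacing, moved)))

    # candidate initial rotations from principal axes (sign-ambiguous)
    tpl_idx = np.argwhere(template > 0.05)
    tpl_pts = (tpl_idx - (np.array(template.shape) - 1) / 2.0) * spacing
    Vt = _principal_axes(tpl_pts, template[tuple(tpl_idx.T)])
    Vm = _principal_axes(pts)
    candidates = [np.zeros(3)]
    for sx in (1, -1):
        for sy in (1, -1):
            S = np.diag([sx, sy, sx * sy])       # keep det = +1
            Rc = Vt @ S @ Vm.T
            if np.linalg.det(Rc) < 0:
                Rc = -Rc
            candidates.append(Rotation.from_matrix(Rc).as_euler("xyz", degrees=True))
    best0, f0 = None, np.inf
    for c in candidates:
        f = metric(np.concatenate([c, np.zeros(3)]))
        if f < f0:
            best0, f0 = np.concatenate([c, np.zeros(3)]), f

    res = optimize.minimize(metric, best0, method="Powell",
                            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 200})
    improved = bool(res.fun < f0)
    params = res.x if improved else best0
    final = res.fun if improved else f0
    R = Rotation.from_euler("xyz", params[:3], degrees=True).as_matrix()
    return RigidTransform(rotation=R, translation=np.asarray(params[3:], float),
                          centroid=centroid_mm, metric=-final, metric_init=-f0,
                          improved=improved)


def resample_mask(mask: EyeMask, transform: RigidTransform,
                  shape: tuple, spacing=None) -> np.ndarray:
    """Resample the mask through the transform onto a centred template grid.

    Returns a float volume (trilinear interpolation of the binary mask);
    keeping fractional values preserves information for averaging.
    """
    if spacing is None:
        spacing = mask.spacing
    spacing = np.asarray(spacing, dtype=float)
    out_center = (np.array(shape) - 1) / 2.0
    Rinv = transform.rotation.T
    origin = np.asarray(mask.origin)
    # idx_in = (Rinv @ (w - t) + centroid - origin) / spacing,  w = (idx_out - c)*spacing
    A = (Rinv * spacing[None, :]) / spacing[:, None]
    b = (Rinv @ (-out_center * spacing - transform.translation)
         + transform.centroid - origin) / spacing
    return ndimage.affine_transform(mask.data.astype(np.float32), A, offset=b,
                                    output_shape=shape, order=1,
                                    mode="constant", cval=0.0)


def _largest_component(binary: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n <= 1:
        return binary
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def build_group_template(masks, group_label: str | None = None,
                         eye_side: str | None = None, *,
                         smoothing_sigma_mm: float = 0.7,
                         threshold: float = 0.5,
                         all_masks=None,
                         initial_template: np.ndarray | None = None,
                         shape: tuple | None = None) -> EyeTemplate:
    """Two-pass aligned-average template for one group (and one eye side).

    ``all_masks`` (default: the group itself) feeds the global blurry
    template of pass 1; pass 2 re-aligns and averages within the group.  A
    precomputed ``initial_template`` (e.g. the refined global average when
    building several group templates from one cohort) skips pass 1.
    """
    masks = _canonical_order(list(masks))
    if len(masks) < 2:
        raise ValueError("insufficient masks: need at least 2")
    spacing = _check_common_spacing(masks)
    pool = _canonical_order(list(all_masks)) if all_masks is not None else masks
    if shape is None:
        shape = _common_shape(pool if initial_template is None else masks)
    if initial_template is None:
        blurry = ndimage.gaussian_filter(voxelwise_average(pool, shape=shape), 1.0)
        aligned = [resample_mask(m, rigid_align(m, blurry, spacing), shape, spacing)
                   for m in pool]
        refined = np.mean(aligned, axis=0)
    else:
        refined = initial_template
        shape = refined.shape

    group_aligned = [resample_mask(m, rigid_align(m, refined, spacing), shape, spacing)
                     for m in masks]
    prob = np.mean(group_aligned, axis=0)
    smoothed = ndimage.gaussian_filter(prob, smoothing_sigma_mm / spacing)
    final = _largest_component(smoothed >= threshold)
    return EyeTemplate(probability_volume=prob, final_mask=final,
                       voxel_size=tuple(spacing), group_label=group_label,
                       eye_side=eye_side, n_contributing=len(masks))


def export_surface(template: EyeTemplate, path) -> None:
    """Write the final template mask's isosurface as PLY/STL (for rendering)."""
    import trimesh
    from skimage import measure as skmeasure

    vol = np.pad(template.final_mask.astype(np.float32), 1)
    verts, faces, _, _ = skmeasure.marching_cubes(vol, level=0.5,
                                                  spacing=template.voxel_size)
    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(str(path))
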