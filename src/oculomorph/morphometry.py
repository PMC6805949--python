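"""Geometric morphometry of 3-D binary eye masks.

The measurements follow the axis-frame construction used in ocular MRI
shape studies: the *eye axis* is the normal of the corneal tangent plane at
the corneal apex; the *axial plane* is the tilted transverse plane that
contains both the apex and the optic disk; the *axial length* is the
apex-to-posterior-retina distance along the eye axis; the *transverse
length* is the maximum in-axial-plane extent orthogonal to the eye axis;
and the *anisotropy ratio* is axial / transverse (1 for a sphere, > 1 for
an anteroposteriorly elongated, myopia-like globe).

Coordinate convention: mask grid axes map to anatomical directions
(+x = subject's right, +y = anterior, +z = superior), i.e. a RAS frame
with the anterior direction along +y.  All world coordinates are mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure


class InvalidMaskError(ValueError):
    """Mask is empty, fragmented, degenerate, or touches the grid edge."""


class DegenerateLandmarksError(ValueError):
    """Apex and optic-disk landmarks are too close to define an axis."""


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _as_spacing(voxel_size) -> np.ndarray:
    s = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if s.size == 1:
        s = np.repeat(s, 3)
    if s.size != 3 or np.any(s <= 0):
        raise ValueError("voxel_size must be a positive scalar or 3-vector")
    return s


@dataclass
class EyeMask:
    """A binary eye-segmentation volume with physical spacing.

    Parameters
    ----------
    data : (nx, ny, nz) array of bool
        Foreground = eye.  Grid axes are anatomical (+x right, +y anterior,
        +z superior).
    voxel_size : float or (3,) sequence
        Voxel edge lengths in mm (isotropic 0.7 mm is the usual MRI grid).
    origin : (3,) sequence, optional
        World-mm coordinate of the centre of voxel (0, 0, 0).  Defaults to
        placing the grid centre at the world origin.
    eye_side : {"left", "right"}
    landmarks : dict, optional
        Optional known mm landmarks, e.g. ``{"apex": ..., "disk": ...}``.
    """

    data: np.ndarray
    voxel_size: tuple = 0.7
    origin: tuple | None = None
    eye_side: str = "right"
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise InvalidMaskError("mask must be a 3-D volume")
        self.voxel_size = tuple(_as_spacing(self.voxel_size))
        if self.origin is None:
            c = (np.array(self.data.shape) - 1) / 2.0
            self.origin = tuple(-c * self.spacing)
        else:
            self.origin = tuple(np.asarray(self.origin, dtype=float))
        if self.eye_side not in ("left", "right"):
            raise ValueError("eye_side must be 'left' or 'right'")
        self.landmarks = {
            k: np.asarray(v, dtype=float) for k, v in (self.landmarks or {}).items()
        }

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.voxel_size, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal RAS)."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def world(self, idx: np.ndarray) -> np.ndarray:
        """World-mm coordinates of (possibly fractional) voxel indices."""
        return np.asarray(idx, dtype=float) * self.spacing + np.asarray(self.origin)

    def index(self, pts_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world-mm points."""
        return (np.asarray(pts_mm, dtype=float) - np.asarray(self.origin)) / self.spacing

    def centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.data)
        if idx.size == 0:
            raise InvalidMaskError("invalid mask: empty")
        return self.world(idx.mean(axis=0))

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))

    def validate(self) -> None:
        """Enforce the mask invariants.

        Exactly one 26-connected foreground component of >= 2 voxels, and the
        foreground touches no face of the grid (otherwise the surface could
        not be closed).
        """
        n_fg = int(self.data.sum())
        if n_fg == 0:
            raise InvalidMaskError("invalid mask: empty")
        _, n_comp = ndimage.label(self.data, structure=_CONN26)
        if n_comp != 1:
            raise InvalidMaskError(
                f"invalid mask: {n_comp} connected components (expected 1)"
            )
        for ax in range(3):
            first = np.take(self.data, 0, axis=ax)
            last = np.take(self.data, -1, axis=ax)
            if first.any() or last.any():
                raise InvalidMaskError("invalid mask: foreground touches grid boundary")


@dataclass
class AxisFrame:
    """Eye axis and axial plane derived from the corneal apex and optic disk."""

    apex: np.ndarray
    disk: np.ndarray
    eye_axis: np.ndarray          # unit, points posteriorly (apex -> globe)
    plane_point: np.ndarray       # a point of the axial plane (the apex)
    plane_normal: np.ndarray      # unit normal of the axial plane


@dataclass
class MorphometryResult:
    volume: float                 # mm^3, voxel-count volume
    axial_length: float           # mm
    transverse_length: float      # mm
    anisotropy: float             # axial / transverse
    frame: AxisFrame


# ---------------------------------------------------------------------------
# surface extraction and landmarks
# ---------------------------------------------------------------------------

def extract_surface(mask: EyeMask):
    """Closed triangulated isosurface (level 0.5) of the binary mask.

    Returns ``(vertices, faces)`` with vertices in world mm.  The volume is
    zero-padded by one voxel so the marching-cubes surface is always closed.
    """
    mask.validate()
    if int(mask.data.sum()) < 2:
        raise InvalidMaskError("invalid mask: single-voxel mask has a degenerate surface")
    vol = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = _skmeasure.marching_cubes(vol, level=0.5, spacing=tuple(mask.spacing))
    # undo the 1-voxel pad, then map to world coordinates
    verts = verts - mask.spacing + np.asarray(mask.origin)
    return verts, faces


def find_corneal_apex(mask: EyeMask, surface=None) -> np.ndarray:
    """Surface point of maximal anterior (+y) coordinate.

    On a digitised mask the anterior cap is a flat voxel face, so the maximal
    coordinate is attained by many vertices; the apex is the centroid of the
    tied set, which lands on the cap centre (the anatomical apex).
    """
    verts = surface[0] if surface is not None else extract_surface(mask)[0]
    ymax = verts[:, 1].max()
    tied = verts[np.abs(verts[:, 1] - ymax) < 1e-6]
    return tied.mean(axis=0)


def find_optic_disk(mask: EyeMask, apex=None, surface=None) -> np.ndarray:
    """Optic-disk point: supplied landmark, else the posterior pole.

    A binary mask carries no disk anatomy, so without a landmark the disk is
    approximated by the surface point farthest (Euclidean) from the apex,
    i.e. the posterior pole.
    """
    if "disk" in mask.landmarks:
        return np.asarray(mask.landmarks["disk"], dtype=float)
    verts = surface[0] if surface is not None else extract_surface(mask)[0]
    if apex is None:
        apex = find_corneal_apex(mask, surface=(verts, None))
    d = np.linalg.norm(verts - apex, axis=1)
    # the distance field is flat near the antipode while staircase noise is
    # ~half a voxel, so take the centroid of the near-maximal set
    near = verts[d >= d.max() - 0.5 * float(np.min(mask.spacing))]
    return near.mean(axis=0)


_ML_AXIS = np.array([1.0, 0.0, 0.0])   # mediolateral (left-right) world axis
_SI_AXIS = np.array([0.0, 0.0, 1.0])


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def build_axis_frame(mask: EyeMask, apex=None, disk=None,
                     cap_radius_mm: float = 4.0) -> AxisFrame:
    """Construct the eye axis and the axial plane.

    The corneal tangent plane is the total-least-squares plane fitted to
    surface points within ``cap_radius_mm`` of the apex; the eye axis is its
    normal through the apex, oriented toward the mask centroid (posterior).
    The axial plane contains apex and disk and spans the apex->disk line and
    the mediolateral direction (its normal is orthogonal to left-right).
    """
    surface = extract_surface(mask)
    if apex is None:
        apex = find_corneal_apex(mask, surface=surface)
    apex = np.asarray(apex, dtype=float)
    if disk is None:
        disk = find_optic_disk(mask, apex=apex, surface=surface)
    disk = np.asarray(disk, dtype=float)

    if np.linalg.norm(disk - apex) < 5.0:
        raise DegenerateLandmarksError(
            "degenerate landmarks: apex and disk closer than 5 mm"
        )

    verts = surface[0]
    cap = verts[np.linalg.norm(verts - apex, axis=1) <= cap_radius_mm]
    if len(cap) < 8:   # extremely coarse grid; widen once
        cap = verts[np.linalg.norm(verts - apex, axis=1) <= 2 * cap_radius_mm]
    centered = cap - cap.mean(axis=0)
    # TLS plane normal = singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    centroid = mask.centroid_mm()
    if np.dot(normal, centroid - apex) < 0:
        normal = -normal
    eye_axis = _unit(normal)

    d = _unit(disk - apex)
    pn = np.cross(d, _ML_AXIS)
    if np.linalg.norm(pn) < 1e-6:   # apex->disk parallel to L-R axis (pathological)
        pn = np.cross(d, _SI_AXIS)
    plane_normal = _unit(pn)
    return AxisFrame(apex=apex, disk=disk, eye_axis=eye_axis,
                     plane_point=apex, plane_normal=plane_normal)


# ---------------------------------------------------------------------------
# length measurements (subvoxel, on the interpolated 0.5 isosurface)
# ---------------------------------------------------------------------------

def _sample(mask: EyeMask, pts_mm: np.ndarray) -> np.ndarray:
    """Trilinear sample of the binary volume at world-mm points."""
    vol = mask.__dict__.get("_fvol")
    if vol is None or vol.shape != mask.data.shape:
        vol = mask.data.astype(np.float32)
        mask.__dict__["_fvol"] = vol
    idx = mask.index(pts_mm)
    return ndimage.map_coordinates(vol, idx.T, order=1, mode="constant", cval=0.0)


def _refine_crossing(mask, p0, direction, t_in, t_out, iters=16):
    """Bisect for the 0.5 level between an inside and an outside offset."""
    for _ in range(iters):
        tm = 0.5 * (t_in + t_out)
        v = _sample(mask, (p0 + tm * direction)[None, :])[0]
        if v >= 0.5:
            t_in = tm
        else:
            t_out = tm
    return 0.5 * (t_in + t_out)


def _last_crossing(mask, p0, direction, ts):
    """Distance along the ray p0 + t*direction to the last 0.5-crossing."""
    pts = p0[None, :] + ts[:, None] * direction[None, :]
    vals = _sample(mask, pts)
    inside = vals >= 0.5
    if not inside[1:].any():
        return None
    i = int(np.max(np.nonzero(inside)[0]))
    if i == len(ts) - 1:
        raise ValueError("axis leaves mask: ray exits the grid while inside")
    return _refine_crossing(mask, p0, direction, ts[i], ts[i + 1])


def measure_axial_length(mask: EyeMask, frame: AxisFrame, step: float = 0.05,
                         bundle_radius: float = 0.3) -> float:
    """Apex-to-posterior-retina distance along the eye axis (mm).

    The *last* intersection of the posterior ray with the isosurface is
    used, which is robust to local concavities (e.g. peripapillary bumps).
    A single digitised crossing carries up to half-voxel staircase noise, so
    the crossing distance is averaged over a small bundle of parallel rays
    (offsets within ``bundle_radius`` of the axis; the posterior surface is
    locally orthogonal to the axis there).
    """
    tmax = float(np.linalg.norm(np.array(mask.data.shape) * mask.spacing)) + 1.0
    ts = np.arange(0.0, tmax, step)
    w0 = _unit(np.cross(frame.eye_axis,
                        _SI_AXIS if abs(frame.eye_axis[2]) < 0.9 else _ML_AXIS))
    w1 = _unit(np.cross(frame.eye_axis, w0))
    r = bundle_radius
    offsets = [(0.0, 0.0), (r, 0.0), (-r, 0.0), (0.0, r), (0.0, -r),
               (r, r), (r, -r), (-r, r), (-r, -r)]
    hits = []
    for a, b in offsets:
        t = _last_crossing(mask, frame.apex + a * w0 + b * w1, frame.eye_axis, ts)
        if t is not None:
            hits.append(t)
    if not hits:
        raise ValueError("axis leaves mask: no posterior intersection")
    return float(np.mean(hits))


def _chord(mask, origin, direction, smax, coarse=0.05):
    """Extent of the mask along the line origin + s*direction, subvoxel ends."""
    ss = np.arange(-smax, smax + coarse, coarse)
    pts = origin[None, :] + ss[:, None] * direction[None, :]
    inside = _sample(mask, pts) >= 0.5
    if not inside.any():
        return 0.0
    i0 = int(np.argmax(inside))
    i1 = len(inside) - 1 - int(np.argmax(inside[::-1]))
    lo = ss[i0] if i0 == 0 else _refine_crossing(mask, origin, direction, ss[i0], ss[i0 - 1])
    hi = ss[i1] if i1 == len(ss) - 1 else _refine_crossing(mask, origin, direction, ss[i1], ss[i1 + 1])
    return float(hi - lo)


def _max_chord_profile(mask, frame, w, ts, smax):
    """Maximum of the chord-length profile c(t) along the axis, denoised.

    On a digitised mask each chord end carries ~half-voxel staircase noise;
    taking the raw maximum over many axis positions would be biased upward
    by the extreme-value of that noise.  The profile of a smooth globe is
    locally quadratic around its maximum, so the maximum is estimated by a
    least-squares parabola over the positions near the coarse argmax (raw
    maximum as fallback for degenerate fits).
    """
    chords = np.array([_chord(mask, frame.apex + t * frame.eye_axis, w, smax)
                       for t in ts])
    if not (chords > 0).any():
        return 0.0
    j = int(np.argmax(chords))
    window = (np.abs(ts - ts[j]) <= 2.8) & (chords > 0)
    if window.sum() >= 5:
        coef = np.polyfit(ts[window], chords[window], 2)
        if coef[0] < 0:
            t_vertex = -coef[1] / (2 * coef[0])
            if ts[window].min() <= t_vertex <= ts[window].max():
                return float(np.polyval(coef, t_vertex))
    return float(chords[j])


def measure_transverse_length(mask: EyeMask, frame: AxisFrame,
                              axial_length: float | None = None,
                              step_t: float = 0.35,
                              transverse_3d: bool = False) -> float:
    """Maximum extent orthogonal to the eye axis (mm).

    By default the search is confined to the axial plane (the chord direction
    is the in-plane vector orthogonal to the eye axis), maximised over
    positions along the axis.  With ``transverse_3d`` the chord direction is
    additionally swept around the axis and the 3-D maximum is returned.
    """
    if axial_length is None:
        axial_length = measure_axial_length(mask, frame)
    if transverse_3d:
        angles = np.deg2rad(np.arange(0.0, 180.0, 10.0))
        w0 = _unit(np.cross(frame.plane_normal, frame.eye_axis))
        w1 = _unit(np.cross(frame.eye_axis, w0))
        dirs = [np.cos(a) * w0 + np.sin(a) * w1 for a in angles]
    else:
        dirs = [_unit(np.cross(frame.plane_normal, frame.eye_axis))]

    smax = float(np.linalg.norm(np.array(mask.data.shape) * mask.spacing)) / 2 + 1.0
    ts = np.arange(-1.0, axial_length + 1.0 + step_t, step_t)
    best = max(_max_chord_profile(mask, frame, w, ts, smax) for w in dirs)
    if best <= 0:
        raise ValueError("axis leaves mask: empty cross-sections")
    return best


def compute_volume(mask: EyeMask) -> float:
    """Foreground voxel count x voxel volume (mm^3).

    Deliberately the voxel-count volume (not a surface-mesh volume): it is
    what threshold-contour segmentation tools report.
    """
    mask.validate()
    return mask.volume_mm3()


def measure_eye(mask: EyeMask, transverse_3d: bool = False,
                use_landmarks: bool = True) -> MorphometryResult:
    """Full morphometry: volume, axial and transverse lengths, anisotropy.

    Known landmarks attached to the mask (corneal apex, optic disk) take
    precedence over their image-derived fallbacks, mirroring how the real
    protocol marks both points on the anatomy rather than inferring them
    from the silhouette.
    """
    mask.validate()
    apex = mask.landmarks.get("apex") if use_landmarks else None
    frame = build_axis_frame(mask, apex=apex)
    axial = measure_axial_length(mask, frame)
    transverse = measure_transverse_length(mask, frame, axial_length=axial,
                                           transverse_3d=transverse_3d)
    return MorphometryResult(
        volume=compute_volume(mask),
        axial_length=axial,
        transverse_length=transverse,
        anisotropy=axial / transverse,
        frame=frame,
    )
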