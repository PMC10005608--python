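"""Rigid alignment of each grain to a canonical frame.

The canonical frame has the crease axis vertical (+z), the two lobes along
y, the crease on the -x side, and the grain centroid at the image centre.
The crease axis is traced slice by slice as the deepest convexity defect of
the cross-section contour; a robust line fit to those tips gives the
longitudinal axis, in-plane second moments of the central slices give the
lobe direction, and the centroid fixes the translation.

All vectors and matrices act on (z, y, x) index coordinates.  Rotations are
taken about the geometric grid centre ``(shape - 1) / 2``; translations are
in voxels and applied after the rotation:

    p_out = R @ (p_in - c_in) + c_out + t
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from . import _poly
from .io_prep import Volume
from .segmentation import Mask

__all__ = [
    "RigidTransform",
    "CreaseTrace",
    "detect_crease_tips",
    "compute_alignment",
    "apply_transform",
    "euler_zyx_to_matrix",
    "matrix_to_euler_zyx",
    "rotation_angle_deg",
]


# ---------------------------------------------------------------------------
# rotations in (z, y, x) index space

def _rot_z(a: float) -> np.ndarray:
    """Rotation about the z axis (mixes y and x)."""
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def euler_zyx_to_matrix(angles_deg) -> np.ndarray:
    """Intrinsic Z-Y-X Euler angles (degrees) to a rotation matrix."""
    a, b, c = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return _rot_z(a) @ _rot_y(b) @ _rot_x(c)


def matrix_to_euler_zyx(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_zyx_to_matrix` (degrees; gimbal-safe branch)."""
    R = np.asarray(R, dtype=float)
    sb = np.clip(R[0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    if abs(abs(sb) - 1.0) > 1e-9:
        a = np.arctan2(-R[1, 2], R[2, 2])
        c = np.arctan2(-R[0, 1], R[0, 0])
    else:  # gimbal lock: fold everything into the z angle
        a = np.arctan2(sb * R[1, 0], R[1, 1])
        c = 0.0
    return tuple(np.rad2deg([a, b, c]))  # type: ignore[return-value]


def rotation_angle_deg(R: np.ndarray) -> float:
    """Geodesic angle of a rotation matrix, degrees."""
    tr = float(np.trace(np.asarray(R)))
    return float(np.rad2deg(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def _minimal_rotation(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Smallest rotation mapping unit vector v_from to v_to (Rodrigues)."""
    a = v_from / np.linalg.norm(v_from)
    b = v_to / np.linalg.norm(v_to)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 deg about any perpendicular axis
        perp = np.eye(3)[np.argmin(np.abs(a))]
        perp = perp - (perp @ a) * a
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


@dataclass
class RigidTransform:
    """Rotation + translation mapping the acquisition frame to the aligned frame.

    Applied as ``p_out = R @ (p_in - c_in) + c_out + translation`` with c the
    grid centres; see module docstring.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler_zyx(cls, angles_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(euler_zyx_to_matrix(angles_deg), np.asarray(translation, float))

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """self ∘ first (apply ``first``, then ``self``; equal grid centres)."""
        return RigidTransform(
            self.rotation @ first.rotation,
            self.rotation @ first.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def transform_points(self, pts: np.ndarray, shape) -> np.ndarray:
        """Map (N, 3) points, same input/output grid shape."""
        c = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        pts = np.asarray(pts, dtype=float)
        return (self.rotation @ (pts - c).T).T + c + self.translation

    def euler_zyx(self) -> tuple[float, float, float]:
        return matrix_to_euler_zyx(self.rotation)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["rotation"]).reshape(3, 3), np.array(obj["translation"]))


@dataclass
class CreaseTrace:
    """Per-slice crease-tip positions, (z, y, x) rows with strictly increasing z."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) and np.any(np.diff(self.points[:, 0]) <= 0):
            raise ValueError("crease trace z must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)


def _slice_contour(fg: np.ndarray) -> np.ndarray | None:
    """Sub-pixel outer contour (y, x) of the largest component of a 2D slice."""
    labels, n = ndimage.label(fg)
    if n == 0:
        return None
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    padded = np.pad(fg.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=lambda c: abs(_poly.signed_area(c)))
    pts = contour - 1.0  # unpad
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 4:
        return None
    return _poly.ensure_ccw(pts)


def detect_crease_tips(mask: Mask, min_depth: float = 5.0,
                       min_slice_voxels: int = 25) -> CreaseTrace:
    """Trace the crease tip through the XY slices of a segmented grain.

    Per slice, the crease tip is the contour point of the largest convexity
    defect — the deepest point of the concavity relative to the convex hull.
    Slices whose defect is shallower than ``min_depth`` voxels (convex
    sections, extreme top/bottom) are skipped.
    """
    if not mask.data.any():
        raise ValueError("empty mask")
    pts = []
    for z in range(mask.shape[0]):
        fg = mask.data[z]
        if fg.sum() < min_slice_voxels:
            continue
        contour = _slice_contour(fg)
        if contour is None:
            continue
        tip, depth, _, _ = _poly.deepest_hull_defect(contour)
        if tip < 0 or depth < min_depth:
            continue
        y, x = contour[tip]
        pts.append((float(z), float(y), float(x)))
    if len(pts) < 3:
        raise ValueError("no crease found: fewer than 3 slices with a "
                         f"convexity defect deeper than {min_depth}")
    return CreaseTrace(np.asarray(pts))


def _fit_line_direction(pts: np.ndarray, trim: float = 0.1) -> np.ndarray:
    """First principal component with one robust refit dropping worst residuals."""
    def pca_dir(p):
        centred = p - p.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        return vt[0], p.mean(axis=0)

    d, m = pca_dir(pts)
    resid = np.linalg.norm((pts - m) - np.outer((pts - m) @ d, d), axis=1)
    keep = resid <= np.quantile(resid, 1.0 - trim)
    if keep.sum() >= 3:
        d, _ = pca_dir(pts[keep])
    if d[0] < 0:  # orient along +z
        d = -d
    return d


def compute_alignment(mask: Mask, trace: CreaseTrace,
                      central_fraction: float = 0.5) -> RigidTransform:
    """Estimate the rigid transform bringing the grain to the canonical frame.

    Three steps: (1) total-least-squares line through the crease tips,
    rotated to +z; (2) in-plane rotation about z putting the largest
    principal axis of the central slices' second moments along y, with the
    crease on the -x side; (3) translation of the mask centroid to the image
    centre.
    """
    if len(trace) < 3:
        raise ValueError("crease trace needs at least 3 points")
    shape = np.asarray(mask.shape, dtype=float)
    c = (shape - 1.0) / 2.0

    direction = _fit_line_direction(trace.points)
    R1 = _minimal_rotation(direction, np.array([1.0, 0.0, 0.0]))

    coords = np.argwhere(mask.data).astype(float)
    if len(coords) > 200_000:
        step = len(coords) // 200_000 + 1
        coords = coords[::step]
    rc = (R1 @ (coords - c).T).T

    z = rc[:, 0]
    zlo = z.min() + (1.0 - central_fraction) / 2.0 * (z.max() - z.min())
    zhi = z.max() - (1.0 - central_fraction) / 2.0 * (z.max() - z.min())
    mid = rc[(z >= zlo) & (z <= zhi)]
    inplane = mid[:, 1:] - mid[:, 1:].mean(axis=0)
    cov = inplane.T @ inplane / len(inplane)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]  # (y, x) components of the major axis
    phi = np.arctan2(v[1], v[0])    # angle from the y axis
    R = _rot_z(-phi) @ R1

    # crease tips must sit on the -x side of the centroid
    tips = (R @ (trace.points - c).T).T
    centroid = (R @ (coords.mean(axis=0) - c))
    if tips[:, 2].mean() > centroid[2]:
        R = _rot_z(np.pi) @ R
        centroid = (R @ (coords.mean(axis=0) - c))

    # centroid -> image centre, rounded to whole voxels: sub-voxel centring
    # buys nothing downstream but forces an extra interpolation of the
    # grayscale (which smears sharp void/tissue edges across the fixed
    # porosity threshold when the rotation is negligible)
    translation = -np.round(centroid)
    return RigidTransform(R, translation)


def apply_transform(obj: Volume | Mask, t: RigidTransform,
                    out_shape: tuple[int, int, int] | None = None):
    """Resample a Volume (trilinear) or Mask (nearest) under a rigid transform.

    Inverse-mapping resampling with zero fill outside the source grid.
    """
    in_shape = np.asarray(obj.shape, dtype=float)
    out_shape = tuple(obj.shape) if out_shape is None else tuple(out_shape)
    if any(s <= 0 for s in out_shape):
        raise ValueError("out_shape must be positive")
    c_in = (in_shape - 1.0) / 2.0
    c_out = (np.asarray(out_shape, dtype=float) - 1.0) / 2.0

    Rinv = t.rotation.T
    offset = c_in - Rinv @ (c_out + t.translation)

    if isinstance(obj, Mask):
        out = ndimage.affine_transform(
            obj.data.astype(np.uint8), Rinv, offset=offset,
            output_shape=out_shape, order=0, mode="constant", cval=0)
        return Mask(out > 0, obj.spacing, obj.origin)
    out = ndimage.affine_transform(
        obj.data.astype(np.float64), Rinv, offset=offset,
        output_shape=out_shape, order=1, mode="constant", cval=0.0)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return Volume(out, obj.spacing, obj.origin)
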