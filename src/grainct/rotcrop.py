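"""Arbitrarily oriented crop and resample of a 3D volume.

Used to extract a sub-volume in which a curved surface layer (the epicarp)
becomes roughly parallel to the XY plane: the local z axis is taken from
the mean smoothed intensity gradient around a chosen surface point (the
gradient points from dark background into bright tissue), and the volume is
resampled on a rotated box around that point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_prep import Volume

__all__ = ["OrientedBox", "estimate_orientation", "rotated_crop"]


def _to_xyz(v: np.ndarray) -> np.ndarray:
    return np.asarray(v, dtype=float)[::-1]


def _cross_zyx(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product of (z, y, x)-ordered vectors, right-handed in (x, y, z)."""
    return np.cross(_to_xyz(a), _to_xyz(b))[::-1]


@dataclass
class OrientedBox:
    """Output box: ``center`` (z, y, x) in source voxels, ``size`` output
    voxel counts (z, y, x), ``rotation`` mapping box offsets to source
    offsets (columns = box axes in the source frame)."""

    center: np.ndarray
    size: tuple[int, int, int]
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if any(s <= 0 for s in self.size):
            raise ValueError("box size must be positive")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")


def estimate_orientation(vol: Volume, center, radius: float,
                         grad_tol: float = 1e-3) -> np.ndarray:
    """Local-gradient z axis around a point, completed to a rotation.

    The new z axis is the mean Gaussian-smoothed gradient over the ball
    (sigma = radius / 3), normalized — pointing from dark to bright.  The
    new x axis lies in the plane spanned by the global x axis and the new z
    (falling back to global y when nearly parallel); y completes the
    right-handed frame.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    r = float(radius)
    lo = np.floor(center - r).astype(int)
    hi = np.ceil(center + r).astype(int) + 1
    if np.any(lo < 0) or np.any(hi > np.asarray(vol.shape)):
        raise ValueError("ball around center extends outside the volume")

    margin = int(np.ceil(r)) + 3
    lo_m = np.maximum(np.floor(center - r).astype(int) - margin, 0)
    hi_m = np.minimum(np.ceil(center + r).astype(int) + margin,
                      np.asarray(vol.shape))
    local = vol.data[lo_m[0]:hi_m[0], lo_m[1]:hi_m[1], lo_m[2]:hi_m[2]].astype(float)
    smoothed = ndimage.gaussian_filter(local, sigma=r / 3.0)
    gz, gy, gx = np.gradient(smoothed)

    zz, yy, xx = np.ogrid[lo_m[0]:hi_m[0], lo_m[1]:hi_m[1], lo_m[2]:hi_m[2]]
    ball = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= r * r
    g = np.array([gz[ball].mean(), gy[ball].mean(), gx[ball].mean()])
    norm = np.linalg.norm(g)
    if norm < grad_tol:
        raise ValueError("no gradient: region around the center is uniform")
    z_new = g / norm

    global_x = np.array([0.0, 0.0, 1.0])
    x_cand = global_x - (global_x @ z_new) * z_new
    if np.linalg.norm(x_cand) < 1e-3:
        global_y = np.array([0.0, 1.0, 0.0])
        x_cand = global_y - (global_y @ z_new) * z_new
    x_new = x_cand / np.linalg.norm(x_cand)
    y_new = _cross_zyx(z_new, x_new)
    R = np.column_stack([z_new, y_new, x_new])
    if np.linalg.det(R) < 0:
        R = np.column_stack([z_new, -y_new, x_new])
    return R


def rotated_crop(vol: Volume, box: OrientedBox) -> Volume:
    """Resample the volume on the oriented box (trilinear, zero fill).

    Output voxel (k, j, i) samples the source at
    ``box.center + R @ ((k, j, i) - (size - 1) / 2)``.
    """
    size = np.asarray(box.size, dtype=int)
    c_out = (size - 1.0) / 2.0
    offset = box.center - box.rotation @ c_out
    out = ndimage.affine_transform(
        vol.data.astype(np.float64), box.rotation, offset=offset,
        output_shape=tuple(size), order=1, mode="constant", cval=0.0)
    return Volume(np.clip(np.rint(out), 0, 255).astype(np.uint8),
                  vol.spacing, vol.origin)
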