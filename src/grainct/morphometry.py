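"""Global grain morphometry after alignment.

Dimensions (length, width, thickness, volume) are measured on a cleaned
mask: a morphological opening removes the hairs, 3D hole filling closes the
internal voids, and each extent is the inclusive voxel span times the voxel
size.  A surface-pore counter locates dark openings on the ventral face; it
is heuristic plumbing for screening candidate stomata, not a claim of
biological stoma identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .io_prep import Volume
from .segmentation import Mask

__all__ = ["GrainDimensions", "clean_mask", "measure_dimensions",
           "count_surface_pores"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GrainDimensions:
    """Grain extents in µm: length along z, width along y, thickness along x."""

    length: float
    width: float
    thickness: float
    volume: float

    def as_dict(self) -> dict:
        return {"length": self.length, "width": self.width,
                "thickness": self.thickness, "volume": self.volume}


def clean_mask(mask: Mask, hair_radius: int = 3) -> Mask:
    """Remove thin protrusions (hairs) and fill internal voids.

    Opening with a ball of ``hair_radius`` erases structures thinner than
    the ball; 3D hole filling then closes any internal cavity.
    """
    if not mask.data.any():
        raise ValueError("empty mask")
    if hair_radius > 0:
        cleaned = ndimage.binary_opening(mask.data, structure=ball(hair_radius))
    else:
        cleaned = mask.data.copy()
    cleaned = ndimage.binary_fill_holes(cleaned)
    if not cleaned.any():
        raise ValueError("mask vanished during cleaning; hair_radius too large?")
    return Mask(cleaned, mask.spacing, mask.origin)


def measure_dimensions(mask: Mask) -> GrainDimensions:
    """Per-axis extent = (max index - min index + 1) × spacing; volume in µm³."""
    coords = np.argwhere(mask.data)
    if len(coords) == 0:
        raise ValueError("empty mask")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    spans = (hi - lo + 1).astype(float)
    sz, sy, sx = mask.spacing
    return GrainDimensions(
        length=spans[0] * sz,
        width=spans[1] * sy,
        thickness=spans[2] * sx,
        volume=float(len(coords)) * sz * sy * sx,
    )


def count_surface_pores(
    vol: Volume,
    mask: Mask,
    min_pore_area: int = 5,
    max_pore_area: int = 300,
    dark_threshold: int = 100,
    surface_depth: float = 2.0,
) -> tuple[int, np.ndarray]:
    """Count dark openings on the ventral surface of an aligned grain.

    The outer surface shell of the mask (voxels within ``surface_depth`` of
    the boundary) is scanned for connected below-threshold patches whose
    voxel count lies within [min_pore_area, max_pore_area], restricted to
    the ventral half (x below the mask centroid).  Returns the count and an
    (n, 3) array of patch centroids.
    """
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.data.any():
        return 0, np.zeros((0, 3))
    dist_in = ndimage.distance_transform_edt(mask.data)
    shell = mask.data & (dist_in <= surface_depth)
    cx = np.argwhere(mask.data)[:, 2].mean()
    xs = np.arange(mask.shape[2])[None, None, :]
    ventral = np.broadcast_to(xs < cx, mask.shape)
    candidate = shell & ventral & (vol.data < dark_threshold)
    labels, n = ndimage.label(candidate, structure=_CONN26)
    if n == 0:
        return 0, np.zeros((0, 3))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = np.flatnonzero((sizes >= min_pore_area) & (sizes <= max_pore_area)) + 1
    if keep.size == 0:
        return 0, np.zeros((0, 3))
    centers = np.array(ndimage.center_of_mass(candidate, labels, keep.tolist()))
    return int(keep.size), centers
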