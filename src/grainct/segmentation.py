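"""Binary segmentation of the caryopsis from the mounted-sample volume.

Low-resolution acquisitions contain, besides the grain, the tube and tape
used to hold it; these enter the field of view from outside, so they show up
as bright components touching two or more volume borders.  Segmentation is
threshold + morphology: opening to cut thin bridges, selection of the
largest interior component, morphological reconstruction to restore detail
(hairs) lost to the opening, closing and 3D hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .io_prep import Volume

__all__ = ["Mask", "segment_caryopsis", "apply_mask", "write_mask", "read_mask"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Mask:
    """3D binary grid congruent to a Volume; foreground = caryopsis."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"Mask data must be 3D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_count(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "Mask":
        return Mask(self.data.copy(), self.spacing, self.origin)


def _border_face_counts(labels: np.ndarray, n_labels: int) -> np.ndarray:
    """For each label, number of the 6 volume faces it touches."""
    counts = np.zeros(n_labels + 1, dtype=int)
    faces = [
        labels[0], labels[-1],
        labels[:, 0], labels[:, -1],
        labels[:, :, 0], labels[:, :, -1],
    ]
    for face in faces:
        present = np.unique(face)
        counts[present[present > 0]] += 1
    return counts


def segment_caryopsis(
    vol: Volume,
    threshold: float | None = None,
    opening_radius: int = 2,
    closing_radius: int = 3,
) -> Mask:
    """Segment the caryopsis as a single solid binary component.

    Pipeline: threshold (Otsu when not given) -> morphological opening
    (ball) -> keep the largest connected component that touches at most one
    volume border (tube/tape span >= 2 borders) -> morphological
    reconstruction of that component inside the thresholded foreground ->
    closing -> 3D hole filling.

    Parameters
    ----------
    threshold : manual 8-bit threshold; foreground is ``data >= threshold``.
        Defaults to Otsu's automatic value.
    opening_radius, closing_radius : ball radii in voxels.
    """
    data = vol.data
    if data.max() == data.min():
        raise ValueError("empty foreground: volume is constant")
    if threshold is None:
        threshold = threshold_otsu(data)
    fg = data >= threshold
    if not fg.any():
        raise ValueError("empty foreground after threshold")

    if opening_radius > 0:
        opened = ndimage.binary_opening(fg, structure=ball(opening_radius))
    else:
        opened = fg
    if not opened.any():
        raise ValueError("empty foreground after opening")

    labels, n = ndimage.label(opened, structure=_CONN26)
    face_counts = _border_face_counts(labels, n)
    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64),
                               labels, index=np.arange(1, n + 1))
    interior = np.flatnonzero(face_counts[1:] <= 1) + 1
    if interior.size == 0:
        raise ValueError("no component clear of the volume borders; "
                         "cannot separate the caryopsis from the mounting")
    best = int(interior[np.argmax(sizes[interior - 1])])
    marker = labels == best

    # reconstruct inside the raw thresholded foreground to restore hairs and
    # thin detail removed by the opening
    recon = ndimage.binary_propagation(marker, mask=fg, structure=_CONN26)

    if closing_radius > 0:
        pad = closing_radius + 1
        padded = np.pad(recon, pad)
        padded = ndimage.binary_closing(padded, structure=ball(closing_radius))
        recon = padded[pad:-pad, pad:-pad, pad:-pad]
    filled = ndimage.binary_fill_holes(recon)

    # closing may have re-merged border structures; keep the one component
    labels2, n2 = ndimage.label(filled, structure=_CONN26)
    if n2 > 1:
        sizes2 = ndimage.sum_labels(np.ones_like(labels2, dtype=np.int64),
                                    labels2, index=np.arange(1, n2 + 1))
        filled = labels2 == (1 + int(np.argmax(sizes2)))
    return Mask(filled, vol.spacing, vol.origin)


def apply_mask(vol: Volume, mask: Mask) -> Volume:
    """Zero out background: keep intensities where the mask is set."""
    if vol.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {vol.shape} vs mask {mask.shape}")
    out = np.where(mask.data, vol.data, np.uint8(0))
    return Volume(out, vol.spacing, vol.origin)


def write_mask(mask: Mask, path: str | Path) -> None:
    """Mask as 8-bit 3D TIFF with foreground 255."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.data.astype(np.uint8) * 255,
                     photometric="minisblack")


def read_mask(path: str | Path,
              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Mask:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return Mask(data > 0, spacing)
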