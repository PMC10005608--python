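"""Ventral pericarp porosity mapping via parallel-curve contour regions.

For each aligned XY slice, the grain contour is extracted from the binary
mask and smoothed; the arc between the two lobe extremities (the convex-hull
touch points bracketing the crease) is retained and split at the crease tip
into two halves.  Each half is divided into ten equal-arclength sub-curves,
and each sub-curve is paired with its inward parallel curve at a
stage-dependent offset depth, forming a quadrilateral band region.  The
porosity of a region is the fraction of covered pixels whose grayscale value
falls below a fixed threshold of 140 — voids and intercellular air are dark,
tissue is bright.  Per-slice values are binned into a 50 (relative height)
× 20 (crease-relative position, −10…+10) summary table; maps from several
grains of the same stage are averaged cell-wise.

Porosity values live in [0, 1]; cells covered by no pixel are missing (NaN),
never zero, since zero is a valid porosity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

from . import _poly
from .io_prep import Volume
from .segmentation import Mask

__all__ = [
    "Contour",
    "CurveSegment",
    "PorosityConfig",
    "PorosityMap",
    "extract_contour",
    "smooth_contour",
    "ventral_segment",
    "build_regions",
    "region_porosity",
    "porosity_table",
    "average_maps",
]

logger = logging.getLogger(__name__)

#: offset depth (voxels) of the parallel curve per developmental stage (°DAA);
#: tracks the average pericarp depth at each stage
DEFAULT_DEPTH_BY_STAGE = {50: 25.0, 100: 20.0, 150: 15.0, 200: 12.0, 250: 10.0}


@dataclass
class Contour:
    """Closed 2D polyline, (y, x) vertex rows, counterclockwise, no repeat."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ValueError("contour needs at least 3 vertices")
        self.vertices = _poly.ensure_ccw(self.vertices)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def length(self) -> float:
        return _poly.polyline_length(self.vertices, closed=True)

    def area(self) -> float:
        return abs(_poly.signed_area(self.vertices))

    def as_polygon(self) -> Polygon:
        return Polygon(_poly.to_xy(self.vertices))


@dataclass
class CurveSegment:
    """Open 2D polyline, (y, x) rows; carries its parent contour for
    inward-direction queries."""

    vertices: np.ndarray
    parent: Polygon | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 2:
            raise ValueError("curve segment needs at least 2 vertices")
        if self.length <= 0:
            raise ValueError("curve segment has zero length")

    @property
    def length(self) -> float:
        return _poly.polyline_length(self.vertices, closed=False)


@dataclass
class PorosityConfig:
    """Parameters of the porosity table.

    threshold : 8-bit void threshold; pixels strictly below count as void.
    n_regions_per_half : regions per half-curve (columns per side).
    n_height_bins : rows of the summary table.
    depth_by_stage : parallel-curve offset depth (voxels) per stage in °DAA.
    smoothing_window : circular moving-average window (vertices at 1 px
        resampling); must be odd.
    min_crease_depth : minimum convexity-defect depth (voxels) for a slice
        to contribute.
    """

    threshold: int = 140
    n_regions_per_half: int = 10
    n_height_bins: int = 50
    depth_by_stage: dict = field(default_factory=lambda: dict(DEFAULT_DEPTH_BY_STAGE))
    smoothing_window: int = 7
    min_crease_depth: float = 5.0

    def validate(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must be an 8-bit value")
        if self.n_regions_per_half < 1:
            raise ValueError("n_regions_per_half must be >= 1")
        if any(d <= 0 for d in self.depth_by_stage.values()):
            raise ValueError("offset depths must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


@dataclass
class PorosityMap:
    """Summary grid: rows = relative height 0 (bottom) … 1 (top); columns =
    crease-relative positions −n…−1, +1…+n.  Missing cells are NaN."""

    values: np.ndarray
    counts: np.ndarray
    stage: int | None = None
    config: PorosityConfig | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.values.shape != self.counts.shape:
            raise ValueError("values and counts shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def column_labels(self) -> list[int]:
        n = self.values.shape[1] // 2
        return list(range(-n, 0)) + list(range(1, n + 1))

    def grand_mean(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(self.values))

    def to_csv(self, path: str | Path) -> None:
        """50×20 CSV, missing = empty cell, plus a JSON sidecar header."""
        import pandas as pd

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.values, columns=self.column_labels())
        df.to_csv(path, index=False, na_rep="")
        header = {
            "stage": self.stage,
            "config": None if self.config is None else {
                "threshold": self.config.threshold,
                "n_regions_per_half": self.config.n_regions_per_half,
                "n_height_bins": self.config.n_height_bins,
                "depth_by_stage": {str(k): v for k, v in
                                   self.config.depth_by_stage.items()},
                "smoothing_window": self.config.smoothing_window,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    def to_png(self, path: str | Path, vmax: float = 0.3) -> None:
        """Heat map with the 0–vmax display range (blue = no void)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 7))
        im = ax.imshow(self.values, origin="lower", aspect="auto",
                       vmin=0.0, vmax=vmax, cmap="viridis",
                       extent=(-0.5, self.values.shape[1] - 0.5, 0.0, 1.0))
        ax.set_xlabel("crease-relative position")
        ax.set_ylabel("relative height")
        n = self.values.shape[1] // 2
        ax.set_xticks([0, n - 1, n, 2 * n - 1])
        ax.set_xticklabels([-n, -1, 1, n])
        fig.colorbar(im, ax=ax, label="porosity")
        fig.savefig(path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# contour operations

def extract_contour(mask_slice: np.ndarray) -> Contour:
    """Sub-pixel boundary of the largest foreground component, CCW."""
    fg = np.asarray(mask_slice).astype(bool)
    if not fg.any():
        raise ValueError("empty slice")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    padded = np.pad(fg.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no contour found")
    pts = max(contours, key=lambda c: abs(_poly.signed_area(c))) - 1.0
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # shrinkage-free regularization of the marching-squares staircase
    pts = _poly.taubin_smooth(pts)
    return Contour(pts)


def smooth_contour(c: Contour, window: int) -> Contour:
    """Resample to 1 px arclength spacing, then circular moving average."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    pts = _poly.resample_closed(c.vertices, spacing=1.0)
    if window > len(pts):
        raise ValueError(f"window {window} exceeds vertex count {len(pts)}")
    if window > 1:
        pts = np.column_stack([
            ndimage.uniform_filter1d(pts[:, k], size=window, mode="wrap")
            for k in range(2)
        ])
    return Contour(pts)


def ventral_segment(c: Contour, min_depth: float = 3.0
                    ) -> tuple[CurveSegment, CurveSegment]:
    """Split the ventral arc at the crease tip into two halves.

    The lobe extremities are the two convex-hull touch points bracketing the
    deepest convexity defect; the retained arc runs between them through the
    crease tip.  Both halves are ordered from the crease tip outward.
    """
    pts = c.vertices
    tip, depth, i1, i2 = _poly.deepest_hull_defect(pts)
    if tip < 0 or depth < min_depth:
        raise ValueError("no crease: contour has no qualifying concavity")
    n = len(pts)
    poly = c.as_polygon()

    def arc(a: int, b: int, step: int) -> np.ndarray:
        idx = [a]
        i = a
        while i != b:
            i = (i + step) % n
            idx.append(i)
        return pts[idx]

    half_back = arc(tip, i1, -1)   # tip -> one lobe extremity
    half_fwd = arc(tip, i2, +1)    # tip -> other lobe extremity
    return (CurveSegment(half_back, parent=poly),
            CurveSegment(half_fwd, parent=poly))


def _inward_sign(mid: np.ndarray, normal: np.ndarray,
                 parent: Polygon | None, inward_ref: np.ndarray | None,
                 probe: float = 2.0) -> float:
    """+1/-1 so that mid + sign*probe*normal points toward the interior."""
    if parent is not None:
        p_plus = shapely.Point(mid[1] + probe * normal[1], mid[0] + probe * normal[0])
        p_minus = shapely.Point(mid[1] - probe * normal[1], mid[0] - probe * normal[0])
        in_plus = parent.contains(p_plus)
        in_minus = parent.contains(p_minus)
        if in_plus != in_minus:
            return 1.0 if in_plus else -1.0
        # both or neither inside (deep concavity): fall back to distance
        d_plus = parent.exterior.distance(p_plus)
        d_minus = parent.exterior.distance(p_minus)
        if in_plus and in_minus:
            return 1.0 if d_plus >= d_minus else -1.0
    if inward_ref is not None:
        return 1.0 if float((inward_ref - mid) @ normal) >= 0 else -1.0
    raise ValueError("cannot determine inward direction: provide a parent "
                     "contour or inward_ref")


def build_regions(half: CurveSegment, n: int, depth: float,
                  inward_ref=None) -> list[Polygon]:
    """Quadrilateral bands between n equal-arclength sub-curves and their
    inward parallel curves at the given offset depth.

    The parallel curve translates each vertex along its inward normal
    (toward the mask interior) by ``depth``.  Self-intersecting offsets at
    tight curvature are repaired by clipping the loops (with a logged
    warning).  Regions are returned crease-first (in the order of the
    half-curve, which starts at the crease tip).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    q = max(8, int(np.ceil(half.length / n)))
    pts = _poly.resample_open(half.vertices, n * q + 1)
    # per-vertex unit normals from central-difference tangents; tangents are
    # lightly smoothed so residual pixel jaggedness cannot fold the offset
    tang = np.gradient(pts, axis=0)
    tw = min(7, max(1, len(pts) // 4))
    if tw > 1:
        tang = np.column_stack([
            ndimage.uniform_filter1d(tang[:, k], size=tw, mode="nearest")
            for k in range(2)
        ])
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])

    ref = None if inward_ref is None else np.asarray(inward_ref, dtype=float)
    regions: list[Polygon] = []
    for k in range(n):
        sub = pts[k * q:(k + 1) * q + 1]
        nrm = normals[k * q:(k + 1) * q + 1]
        mid = sub[len(sub) // 2]
        sign = _inward_sign(mid, nrm[len(nrm) // 2], half.parent, ref)
        offset = sub + sign * depth * nrm
        ring = np.vstack([sub, offset[::-1]])
        poly = Polygon(_poly.to_xy(ring))
        if not poly.is_valid:
            logger.debug("self-intersecting offset band (region %d); "
                         "clipping loops", k)
            global _repaired_bands
            _repaired_bands += 1
            poly = poly.buffer(0)
            if poly.geom_type == "MultiPolygon":
                poly = max(poly.geoms, key=lambda g: g.area)
        regions.append(poly)
    return regions


#: running count of offset bands repaired by loop clipping (see build_regions)
_repaired_bands = 0


def region_porosity(gray_slice: np.ndarray, polygon: Polygon,
                    threshold: int) -> float | None:
    """Fraction of pixels with centre inside the polygon whose value is
    below the threshold; None when no pixel centre is covered."""
    if polygon.is_empty or polygon.area <= 0:
        return None
    gray_slice = np.asarray(gray_slice)
    minx, miny, maxx, maxy = polygon.bounds
    x0 = max(int(np.ceil(minx)), 0)
    x1 = min(int(np.floor(maxx)), gray_slice.shape[1] - 1)
    y0 = max(int(np.ceil(miny)), 0)
    y1 = min(int(np.floor(maxy)), gray_slice.shape[0] - 1)
    if x1 < x0 or y1 < y0:
        return None
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    inside = shapely.contains_xy(polygon, xs.ravel(), ys.ravel())
    if not inside.any():
        return None
    vals = gray_slice[ys.ravel()[inside], xs.ravel()[inside]]
    return float(np.mean(vals < threshold))


def porosity_table(gray: Volume, mask: Mask, cfg: PorosityConfig,
                   stage: int) -> PorosityMap:
    """Build the 50×20 porosity summary table of one aligned grain.

    Rows are relative heights (row 0 at the bottom of the grain); columns
    are crease-relative positions −n…−1 on the −y side (crease-adjacent
    last) and +1…+n on the +y side (crease-adjacent first).
    """
    cfg.validate()
    if gray.shape != mask.shape:
        raise ValueError("grayscale and mask shapes differ")
    if stage not in cfg.depth_by_stage:
        raise ValueError(f"no offset depth configured for stage {stage} °DAA")
    depth = cfg.depth_by_stage[stage]
    nbins, nreg = cfg.n_height_bins, cfg.n_regions_per_half

    zs = np.flatnonzero(mask.data.any(axis=(1, 2)))
    if len(zs) == 0:
        raise ValueError("empty mask")
    z_min, z_max = int(zs.min()), int(zs.max())
    span = z_max - z_min + 1

    sums = np.zeros((nbins, 2 * nreg))
    counts = np.zeros((nbins, 2 * nreg), dtype=int)
    usable = 0
    repaired_before = _repaired_bands
    for z in range(z_min, z_max + 1):
        fg = mask.data[z]
        if fg.sum() < 25:
            continue
        try:
            contour = smooth_contour(extract_contour(fg), cfg.smoothing_window)
            half_a, half_b = ventral_segment(contour, cfg.min_crease_depth)
        except ValueError:
            continue
        # assign halves to the -y / +y side by their outer-end y coordinate
        if half_a.vertices[-1, 0] > half_b.vertices[-1, 0]:
            half_neg, half_pos = half_b, half_a
        else:
            half_neg, half_pos = half_a, half_b
        hb = min(int(nbins * (z - z_min) / span), nbins - 1)
        usable += 1
        for side, half in ((0, half_neg), (1, half_pos)):
            regions = build_regions(half, nreg, depth)
            for k, poly in enumerate(regions):
                p = region_porosity(gray.data[z], poly, cfg.threshold)
                if p is None:
                    continue
                # crease-first region k: -y side fills columns n-1 … 0,
                # +y side fills columns n … 2n-1
                col = (nreg - 1 - k) if side == 0 else (nreg + k)
                sums[hb, col] += p
                counts[hb, col] += 1
    if usable == 0:
        raise ValueError("no usable slice: no crease detected anywhere")
    repaired = _repaired_bands - repaired_before
    if repaired:
        logger.warning("%d of %d offset bands self-intersected at tight "
                       "curvature and were repaired by loop clipping",
                       repaired, usable * 2 * nreg)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PorosityMap(values, counts, stage=stage, config=cfg)


def average_maps(maps: list[PorosityMap]) -> PorosityMap:
    """Cell-wise mean across grains; a cell is missing only when missing in
    every map.  Counts accumulate."""
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("porosity maps have mismatching shapes")
    stack = np.stack([m.values for m in maps])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(stack, axis=0)
    counts = np.sum([m.counts for m in maps], axis=0)
    return PorosityMap(values, counts, stage=maps[0].stage, config=maps[0].config)
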