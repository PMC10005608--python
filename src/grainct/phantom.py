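"""Synthetic caryopsis µCT phantom with exhaustive ground truth.

The phantom emulates the anatomy a low-resolution synchrotron scan shows:
a bright two-lobed pericarp shell around a mid-gray interior (seed + embryo
sac), a deep ventral crease, dark intercellular/PCD voids of controllable
volume fraction in the ventral shell band, stomatal channels opening on the
ventral face into small internal air chambers, thin bright hairs at the top,
an optional bright tape slab touching the volume border, Gaussian noise and
an optional ring artefact.

Geometry: the grain body is the union of two overlapping prolate ellipsoids
(the lobes, offset along y) minus a ventral V-shaped wedge (the crease)
whose tip locus is a vertical line — so the canonical phantom's crease axis
is exactly +z.  Everything has an analytic inside-test, and the truth record
carries brute-force voxel counts, so every downstream stage has an oracle.

All randomness flows from ``PhantomSpec.seed``; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .alignment import RigidTransform, apply_transform
from .io_prep import Volume
from .segmentation import Mask

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "misalign"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic caryopsis.

    Attributes
    ----------
    shape : voxel counts (z, y, x).
    semi_axes : grain body half-extents (z, y, x) in voxels.
    crease_depth : crease depth as a fraction of the grain x-extent, in (0, 0.6].
    shell_thickness : pericarp shell thickness, voxels.
    void_fraction : target porosity of the ventral shell band, in [0, 1].
    void_radius_range : (min, max) void sphere radius, voxels.
    n_stomata : number of stomatal channels on the ventral face.
    hair_count, hair_length : thin bright protrusions at the top.
    tape : add a bright tape-like slab touching the volume border.
    intensity_levels : 8-bit (background, interior, shell, tape) levels.
    noise_sd : additive Gaussian noise, 8-bit units.
    ring_artefact : add a bright concentric ring in every slice.
    seed : RNG seed; all randomness derives from it.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    semi_axes: tuple[float, float, float] = (70.0, 55.0, 42.0)
    crease_depth: float = 0.3
    shell_thickness: float = 12.0
    void_fraction: float = 0.0
    void_radius_range: tuple[float, float] = (2.0, 4.0)
    n_stomata: int = 0
    hair_count: int = 0
    hair_length: float = 20.0
    tape: bool = False
    intensity_levels: tuple[int, int, int, int] = (0, 90, 190, 250)
    noise_sd: float = 8.0
    ring_artefact: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.void_fraction <= 1.0:
            raise ValueError(f"void_fraction must be in [0, 1], got {self.void_fraction}")
        if not 0.0 < self.crease_depth <= 0.6:
            raise ValueError(f"crease_depth must be in (0, 0.6], got {self.crease_depth}")
        bg, interior, shell, tape = self.intensity_levels
        if not (bg < interior < shell):
            raise ValueError("intensity levels must satisfy background < interior < shell")
        az, ay, ax = self.semi_axes
        for a, n, name in zip((az, ay, ax), self.shape, "zyx"):
            if 2 * a + 4 > n:
                raise ValueError(f"semi-axis {name}={a} does not fit inside shape {n}")
        lobe_min = min(az, 0.62 * ay, ax)
        if self.shell_thickness >= lobe_min:
            raise ValueError(
                f"infeasible geometry: shell thickness {self.shell_thickness} "
                f">= lobe radius {lobe_min:.1f}")
        if self.void_radius_range[0] > self.void_radius_range[1]:
            raise ValueError("void_radius_range must be (min, max)")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom.

    ``transform`` is the rigid transform that realigns the volume to the
    canonical frame (identity for a freshly generated phantom; updated by
    :func:`misalign`).  ``per_region_porosity`` holds brute-force void
    fractions of the ventral shell band in 50 height bins × 2 lobe sides;
    ``band_void_fraction`` is the overall band value.  ``dimensions`` are
    the solid-body extents (after hair removal, voids filled), in voxels.
    """

    mask: Mask
    transform: RigidTransform
    per_region_porosity: np.ndarray
    band_void_fraction: float
    stoma_centers: np.ndarray
    dimensions: dict
    crease_line: np.ndarray


def _ellipsoid(zc, yc, xc, az, ay, ax, zz, yy, xx):
    return (((zz - zc) / az) ** 2 + ((yy - yc) / ay) ** 2
            + ((xx - xc) / ax) ** 2) <= 1.0


def _ball_offsets(r: float):
    ri = int(np.ceil(r))
    dz, dy, dx = np.ogrid[-ri:ri + 1, -ri:ri + 1, -ri:ri + 1]
    return (dz * dz + dy * dy + dx * dx) <= r * r, ri


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Generate the synthetic volume and its ground truth.

    Deterministic given ``spec.seed``.  Voids are carved only inside the
    shell band, underneath a sealed one-voxel surface crust; stomatal
    channels are the only openings through the surface and end in a small
    internal air chamber.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    az, ay, ax = spec.semi_axes
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    bg_level, interior_level, shell_level, tape_level = spec.intensity_levels

    zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
    zz, yy, xx = zz.astype(float), yy.astype(float), xx.astype(float)

    # two prolate lobes offset along y
    dy_lobe, by_lobe = 0.38 * ay, 0.62 * ay
    body = (_ellipsoid(cz, cy - dy_lobe, cx, az, by_lobe, ax, zz, yy, xx)
            | _ellipsoid(cz, cy + dy_lobe, cx, az, by_lobe, ax, zz, yy, xx))

    # ventral V-wedge with a z-constant tip line at (cy, x_tip)
    ax_mid = ax * np.sqrt(max(1.0 - (dy_lobe / by_lobe) ** 2, 0.0))
    depth_vox = spec.crease_depth * 2.0 * ax
    x_tip = cx - ax_mid + depth_vox
    if x_tip >= cx + 0.8 * ax:
        raise ValueError("infeasible geometry: crease would cut through the grain")
    wedge = (xx < x_tip) & (np.abs(yy - cy) < 0.55 * (x_tip - xx))
    body_solid = body & ~wedge
    del body, wedge

    # recentre: the crease wedge pulls the centroid dorsally; roll the body
    # by the integer offset so the canonical phantom is centroid-centred
    centroid = np.array(ndimage.center_of_mass(body_solid))
    shift = np.round(centroid - np.array([cz, cy, cx])).astype(int)
    if np.any(shift != 0):
        body_solid = np.roll(body_solid, tuple(-shift), axis=(0, 1, 2))
    crease_y = cy - shift[1]
    x_tip = x_tip - shift[2]
    z_mid = cz - shift[0]

    # pericarp shell band via inward Euclidean distance
    dist_in = ndimage.distance_transform_edt(body_solid)
    shell_band = body_solid & (dist_in <= spec.shell_thickness)
    x_full = np.broadcast_to(xx, (nz, ny, nx))
    ventral_band = shell_band & (x_full < cx)

    # ---- voids: random spheres in the carveable zone (below the crust) ----
    void_mask = np.zeros(spec.shape, dtype=bool)
    band_total = int(ventral_band.sum())
    if spec.void_fraction > 0 and band_total > 0:
        carveable = shell_band & (dist_in >= 2.0)
        target = spec.void_fraction * band_total
        cand = np.argwhere(carveable & (x_full < cx))
        if len(cand) == 0:
            raise ValueError("no carveable shell voxels for voids")
        r0, r1 = spec.void_radius_range
        carved_in_band = 0
        consecutive_rejects = 0
        max_draws = 200 * int(target / max((4 / 3) * np.pi * ((r0 + r1) / 2) ** 3, 1.0) + 100)
        draws = 0
        while carved_in_band < target:
            draws += 1
            if draws > max_draws:
                raise ValueError(
                    f"void_fraction {spec.void_fraction} unreachable in this geometry")
            p = cand[rng.integers(len(cand))]
            r = rng.uniform(r0, r1)
            stamp, ri = _ball_offsets(r)
            sl = tuple(slice(max(c - ri, 0), min(c + ri + 1, n))
                       for c, n in zip(p, spec.shape))
            st = tuple(slice(max(ri - c, 0), ri + 1 + min(n - 1 - c, ri))
                       for c, n in zip(p, spec.shape))
            sphere = stamp[st]
            local_carve = sphere & carveable[sl]
            # non-overlapping by preference; relax when packing saturates
            if void_mask[sl][local_carve].any() and consecutive_rejects < 200:
                consecutive_rejects += 1
                continue
            consecutive_rejects = 0
            newly = local_carve & ~void_mask[sl]
            carved_in_band += int((newly & ventral_band[sl]).sum())
            void_mask[sl] |= local_carve

    # ---- stomata: channels through the crust into an internal chamber ----
    stoma_centers = np.zeros((0, 3))
    stoma_mask = np.zeros(spec.shape, dtype=bool)
    if spec.n_stomata > 0:
        surf = body_solid & (dist_in <= 1.5) & (x_full < cx - 0.25 * ax)
        zc_arr = np.broadcast_to(zz, (nz, ny, nx))
        surf &= (zc_arr > cz - 0.7 * az) & (zc_arr < cz + 0.7 * az)
        surf_pts = np.argwhere(surf)
        if len(surf_pts) == 0:
            raise ValueError("no ventral surface available for stomata")
        gz, gy, gx = np.gradient(ndimage.gaussian_filter(dist_in, 2.0))
        centers = []
        order = rng.permutation(len(surf_pts))
        min_sep = 14.0
        for idx in order:
            p = surf_pts[idx].astype(float)
            if centers and np.min(np.linalg.norm(np.array(centers) - p, axis=1)) < min_sep:
                continue
            centers.append(p)
            if len(centers) == spec.n_stomata:
                break
        if len(centers) < spec.n_stomata:
            raise ValueError(f"could not place {spec.n_stomata} stomata with "
                             f"separation {min_sep}")
        for p in centers:
            iz, iy, ix = (int(round(v)) for v in p)
            n_vec = np.array([gz[iz, iy, ix], gy[iz, iy, ix], gx[iz, iy, ix]])
            nn = np.linalg.norm(n_vec)
            n_vec = n_vec / nn if nn > 1e-9 else np.array([0.0, 0.0, 1.0])
            # channel: radius-1.5 tube from just outside to depth 5
            for t in np.arange(-1.0, 5.0, 0.5):
                q = p + t * n_vec
                stamp, ri = _ball_offsets(1.5)
                qi = np.round(q).astype(int)
                if np.any(qi - ri < 0) or np.any(qi + ri >= spec.shape):
                    continue
                sl = tuple(slice(c - ri, c + ri + 1) for c in qi)
                stoma_mask[sl] |= stamp
            # chamber at depth 7
            q = p + 7.0 * n_vec
            stamp, ri = _ball_offsets(3.0)
            qi = np.round(q).astype(int)
            if not (np.any(qi - ri < 0) or np.any(qi + ri >= spec.shape)):
                sl = tuple(slice(c - ri, c + ri + 1) for c in qi)
                stoma_mask[sl] |= stamp
        stoma_mask &= body_solid
        stoma_centers = np.array(centers, dtype=float)

    # ---- hairs: thin bright protrusions at the top ----
    hair_mask = np.zeros(spec.shape, dtype=bool)
    if spec.hair_count > 0:
        for _ in range(spec.hair_count):
            hy = cy + rng.uniform(-0.5, 0.5) * dy_lobe * 2
            hx = cx + rng.uniform(-0.3, 0.3) * ax
            col = body_solid[:, int(round(hy)), int(round(hx))]
            tops = np.flatnonzero(col)
            if len(tops) == 0:
                continue
            z0 = tops.max()
            tilt = rng.uniform(-0.25, 0.25, size=2)
            for t in np.arange(0.0, spec.hair_length, 0.5):
                q = np.array([z0 + t, hy + t * tilt[0], hx + t * tilt[1]])
                qi = np.round(q).astype(int)
                if np.any(qi < 1) or np.any(qi >= np.array(spec.shape) - 1):
                    break
                hair_mask[qi[0], qi[1], qi[2]] = True
                hair_mask[qi[0], qi[1] + 1, qi[2]] = True
                hair_mask[qi[0], qi[1], qi[2] + 1] = True

    # ---- assemble intensities ----
    img = np.full(spec.shape, float(bg_level))
    img[body_solid & (dist_in > spec.shell_thickness)] = interior_level
    img[shell_band] = shell_level
    img[void_mask] = bg_level
    img[stoma_mask] = bg_level
    img[hair_mask] = shell_level
    if spec.tape:
        img[:, :, 0:3] = tape_level
    if spec.ring_artefact:
        rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        ring = np.broadcast_to(np.abs(rr - 0.30 * min(ny, nx)) < 1.5, spec.shape)
        img[ring] = np.clip(img[ring] + 25.0, 0, 255)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    data = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    # ---- truth ----
    truth_mask = Mask(body_solid | hair_mask)
    band_frac = (float((void_mask & ventral_band).sum()) / band_total
                 if band_total else 0.0)
    per_region = _per_region_truth(void_mask, ventral_band, body_solid, crease_y)
    coords = np.argwhere(body_solid)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    dims = {
        "length": float(hi[0] - lo[0] + 1),
        "width": float(hi[1] - lo[1] + 1),
        "thickness": float(hi[2] - lo[2] + 1),
        "volume": float(len(coords)),
    }
    # crease tip locus: vertical line at (cy, x_tip), restricted to slices
    # where the uncut ventral surface lies at least 2 voxels outside the tip
    crease_pts = []
    for z in range(nz):
        frac = 1.0 - ((z - z_mid) / az) ** 2
        if frac <= 0:
            continue
        x_surf_local = (cx - shift[2]) - ax_mid * np.sqrt(frac)
        if x_surf_local <= x_tip - 2.0:
            crease_pts.append((float(z), crease_y, float(x_tip)))
    crease_line = np.asarray(crease_pts, dtype=float).reshape(-1, 3)

    truth = PhantomTruth(
        mask=truth_mask,
        transform=RigidTransform.identity(),
        per_region_porosity=per_region,
        band_void_fraction=band_frac,
        stoma_centers=stoma_centers,
        dimensions=dims,
        crease_line=crease_line,
    )
    return Volume(data), truth


def _per_region_truth(void_mask, ventral_band, body_solid, cy,
                      n_height_bins: int = 50) -> np.ndarray:
    """Brute-force band porosity per height bin × lobe side."""
    zs = np.flatnonzero(body_solid.any(axis=(1, 2)))
    out = np.full((n_height_bins, 2), np.nan)
    if len(zs) == 0:
        return out
    z_min, z_max = zs.min(), zs.max()
    span = z_max - z_min + 1
    idx = np.argwhere(ventral_band)
    if len(idx) == 0:
        return out
    hb = np.minimum((n_height_bins * (idx[:, 0] - z_min) / span).astype(int),
                    n_height_bins - 1)
    side = (idx[:, 1] >= cy).astype(int)
    voidv = void_mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    for b in range(n_height_bins):
        for s in range(2):
            sel = (hb == b) & (side == s)
            if sel.any():
                out[b, s] = float(voidv[sel].mean())
    return out


def misalign(vol: Volume, truth: PhantomTruth, angles_deg, offset,
             out_shape: tuple[int, int, int] | None = None
             ) -> tuple[Volume, PhantomTruth]:
    """Apply a known rigid misalignment, updating the truth record.

    The returned truth's ``transform`` is exactly what realigns the volume
    (the inverse of the applied misalignment, composed with any transform
    already recorded).
    """
    angles = np.asarray(angles_deg, dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    t_mis = RigidTransform.from_euler_zyx(angles, offset)
    vol2 = apply_transform(vol, t_mis, out_shape)
    mask2 = apply_transform(truth.mask, t_mis, out_shape)
    shape = vol.shape
    truth2 = PhantomTruth(
        mask=mask2,
        transform=truth.transform.compose(t_mis.inverse()),
        per_region_porosity=truth.per_region_porosity.copy(),
        band_void_fraction=truth.band_void_fraction,
        stoma_centers=(t_mis.transform_points(truth.stoma_centers, shape)
                       if len(truth.stoma_centers) else truth.stoma_centers.copy()),
        dimensions=dict(truth.dimensions),
        crease_line=(t_mis.transform_points(truth.crease_line, shape)
                     if len(truth.crease_line) else truth.crease_line.copy()),
    )
    return vol2, truth2
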