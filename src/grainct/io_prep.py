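"""Raw beamline output to calibrated 8-bit volumes, plus quick-look previews.

Synchrotron reconstructions arrive as headerless 32-bit float stacks.  The
first processing step recalibrates intensity linearly onto the 8-bit range
[0, 255] and writes 3D TIFF; mid-slice previews along each axis give a quick
overview of the caryopsis shape.

Axis convention used throughout the package: arrays are indexed (z, y, x)
with z the longitudinal axis (vertical after alignment), y the lobe axis and
x running ventral (crease side, -x) to dorsal (+x).  XY planes are the
cross-sectional slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "Volume",
    "convert_raw",
    "mid_slice_previews",
    "read_raw",
    "read_volume",
    "write_volume",
    "write_previews",
]


@dataclass
class Volume:
    """3D 8-bit grayscale image with voxel spacing.

    Attributes
    ----------
    data : ndarray, uint8, shape (nz, ny, nx)
    spacing : per-axis voxel size in micrometres, order (z, y, x)
    origin : physical offset of voxel (0, 0, 0) in micrometres
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if self.data.dtype != np.uint8:
            raise ValueError(f"Volume data must be uint8, got {self.data.dtype}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)


def convert_raw(raw: np.ndarray, clip_percentile: float = 0.0,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Volume:
    """Recalibrate a 32-bit float volume linearly onto [0, 255].

    The mapping is linear from [lo, hi] to [0, 255] where lo and hi are the
    ``clip_percentile`` and ``1 - clip_percentile`` quantiles of the finite
    values (the min and max when ``clip_percentile`` is 0).  Values outside
    [lo, hi] clamp; rounding is half-away-from-zero.  A constant input maps
    to all zeros.

    Parameters
    ----------
    raw : 3D array of real values (NaNs ignored for the quantiles).
    clip_percentile : fraction in [0, 0.5); quantile clip against hot pixels.
    spacing : voxel size carried onto the output Volume.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 3:
        raise ValueError(f"expected a 3D array, got shape {raw.shape}")
    finite = np.isfinite(raw)
    if not finite.any():
        raise ValueError("raw volume contains no finite value")
    if not 0.0 <= clip_percentile < 0.5:
        raise ValueError(f"clip_percentile must be in [0, 0.5), got {clip_percentile}")

    vals = raw[finite]
    if clip_percentile == 0.0:
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = np.quantile(vals, [clip_percentile, 1.0 - clip_percentile])
    if hi <= lo:
        return Volume(np.zeros(raw.shape, dtype=np.uint8), spacing)

    scaled = (raw - lo) / (hi - lo) * 255.0
    scaled = np.clip(scaled, 0.0, 255.0, out=scaled)
    np.nan_to_num(scaled, copy=False)
    # round half away from zero (values are non-negative here, so +0.5 floor)
    out = np.floor(scaled + 0.5).astype(np.uint8)
    return Volume(out, spacing)


def mid_slice_previews(vol: Volume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Middle slice along each axis, at index floor(n/2).

    Returns
    -------
    (z_slice, y_slice, x_slice) : the YX, ZX and ZY middle planes.
    """
    nz, ny, nx = vol.shape
    return (
        vol.data[nz // 2].copy(),
        vol.data[:, ny // 2].copy(),
        vol.data[:, :, nx // 2].copy(),
    )


def write_previews(vol: Volume, out_dir: str | Path, prefix: str = "preview") -> list[Path]:
    """Write the three mid-slice previews as PNG files."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for axis_name, img in zip("zyx", mid_slice_previews(vol)):
        p = out_dir / f"{prefix}_mid_{axis_name}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths


def read_raw(raw_path: str | Path, sidecar_path: str | Path | None = None) -> np.ndarray:
    """Read a headerless raw float dump using its YAML sidecar.

    Raw beamline dumps carry no header; a sidecar YAML file next to the data
    declares ``shape`` (z, y, x), ``dtype`` (numpy name, default float32
    little-endian) and ``order`` ('C' default).
    """
    raw_path = Path(raw_path)
    if sidecar_path is None:
        sidecar_path = raw_path.with_suffix(".yaml")
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    shape = tuple(int(s) for s in meta["shape"])
    dtype = np.dtype(meta.get("dtype", "<f4"))
    order = meta.get("order", "C")
    data = np.fromfile(raw_path, dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"raw file holds {data.size} values, sidecar shape {shape} "
            f"needs {int(np.prod(shape))}"
        )
    return data.reshape(shape, order=order)


def read_volume(path: str | Path,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Volume:
    """Read an 8-bit 3D TIFF as a Volume."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return Volume(np.asarray(data, dtype=np.uint8), spacing)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a Volume as an 8-bit 3D TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.data, photometric="minisblack")
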