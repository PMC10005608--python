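"""End-to-end orchestration: convert → segment → align → measure → porosity.

A RunConfig mirrors the module defaults, round-trips through YAML, and every
run writes a provenance record (config hash, package version, per-stage
timings) next to the artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import apply_transform, compute_alignment, detect_crease_tips
from .io_prep import Volume, convert_raw, read_raw, read_volume, write_previews, write_volume
from .morphometry import clean_mask, measure_dimensions
from .porosity import PorosityConfig, porosity_table
from .segmentation import apply_mask, segment_caryopsis, write_mask

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults equal the module defaults."""

    input_path: str | None = None
    out_dir: str = "grainct_out"
    stage: int = 250
    clip_percentile: float = 0.001
    threshold: float | None = None
    opening_radius: int = 2
    closing_radius: int = 3
    min_crease_depth: float = 5.0
    hair_radius: int = 3
    porosity: PorosityConfig = field(default_factory=PorosityConfig)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        obj = asdict(self)
        obj["porosity"]["depth_by_stage"] = {
            int(k): float(v) for k, v in obj["porosity"]["depth_by_stage"].items()}
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text())
        por = obj.pop("porosity", None)
        cfg = cls(**obj)
        if por is not None:
            por["depth_by_stage"] = {int(k): float(v)
                                     for k, v in por["depth_by_stage"].items()}
            cfg.porosity = PorosityConfig(**por)
        if isinstance(cfg.spacing, list):
            cfg.spacing = tuple(cfg.spacing)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_input(cfg: RunConfig) -> Volume:
    path = Path(cfg.input_path)
    if not path.exists():
        raise RuntimeError(f"stage convert: input file not found: {path}")
    try:
        if path.suffix in (".tif", ".tiff"):
            return read_volume(path, cfg.spacing)
        raw = read_raw(path)
        return convert_raw(raw, cfg.clip_percentile, cfg.spacing)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage convert: cannot read {path}: {exc}") from exc


def run_pipeline(cfg: RunConfig, vol: Volume | None = None) -> dict:
    """Run the full analysis on one grain and write all artifacts.

    Parameters
    ----------
    vol : optional in-memory input Volume; when None, ``cfg.input_path``
        is read (raw + YAML sidecar, or 3D TIFF).

    Returns
    -------
    dict with keys mask, aligned, aligned_mask, transform, dimensions,
    porosity_map and provenance.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def timed(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage {name}: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    if vol is None:
        vol = timed("convert", _load_input, cfg)
        write_previews(vol, out_dir)

    mask = timed("segment", segment_caryopsis, vol,
                 threshold=cfg.threshold,
                 opening_radius=cfg.opening_radius,
                 closing_radius=cfg.closing_radius)
    masked = apply_mask(vol, mask)

    trace = timed("align", detect_crease_tips, mask, cfg.min_crease_depth)
    transform = compute_alignment(mask, trace)
    aligned_mask = apply_transform(mask, transform)
    aligned = apply_transform(masked, transform)

    cleaned = timed("measure", clean_mask, aligned_mask, cfg.hair_radius)
    dims = measure_dimensions(cleaned)

    pmap = timed("porosity", porosity_table, aligned, aligned_mask,
                 cfg.porosity, cfg.stage)

    # artifacts
    write_mask(mask, out_dir / "mask.tif")
    write_volume(aligned, out_dir / "aligned.tif")
    write_mask(aligned_mask, out_dir / "aligned_mask.tif")
    transform.to_json(out_dir / "transform.json")
    pmap.to_csv(out_dir / "porosity.csv")
    pmap.to_png(out_dir / "porosity.png")
    dims_row = {"stage_daa": cfg.stage, **dims.as_dict()}
    import pandas as pd

    pd.DataFrame([dims_row]).to_csv(out_dir / "dimensions.csv", index=False)

    provenance = {
        "grainct_version": __version__,
        "config_hash": cfg.digest(),
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "timings_s": timings,
        "n_crease_slices": int(len(trace)),
        "numpy_version": np.__version__,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return {
        "mask": mask,
        "aligned": aligned,
        "aligned_mask": aligned_mask,
        "transform": transform,
        "dimensions": dims,
        "porosity_map": pmap,
        "provenance": provenance,
    }
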