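"""Reading and writing the pipeline's file formats.

Label masks are 16/32-bit integer TIFF or PNG images; feature and truth
tables are CSV; simulator configs are YAML.  A CSV sidecar named
``<image>.pixel_size.csv`` (single value) can carry the physical pixel size.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .shape_descriptors import LabelMask
from .vertex_model import ModelParams, Phase, PhaseSchedule

__all__ = [
    "load_mask",
    "save_mask",
    "load_config",
    "save_trajectory",
    "params_from_dict",
    "schedule_from_dict",
]


def _sidecar_pixel_size(path: Path) -> float | None:
    sidecar = path.with_suffix(path.suffix + ".pixel_size.csv")
    if sidecar.exists():
        return float(sidecar.read_text().strip().splitlines()[-1].split(",")[-1])
    return None


def load_mask(path: str | Path, pixel_size: float | None = None) -> LabelMask:
    """Load a label mask from TIFF or PNG; pixel size from the argument, a
    sidecar CSV, or 1.0."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:  # greyscale-saved-as-RGB: take one channel
        arr = arr[..., 0]
    px = pixel_size if pixel_size is not None else (_sidecar_pixel_size(path) or 1.0)
    return LabelMask(arr.astype(np.int32), px)


def save_mask(mask: LabelMask, path: str | Path) -> None:
    path = Path(path)
    arr = mask.pixels
    if arr.max() < 2**16:
        arr = arr.astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    sidecar = path.with_suffix(path.suffix + ".pixel_size.csv")
    sidecar.write_text(f"pixel_size\n{mask.pixel_size}\n")


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def params_from_dict(d: dict) -> ModelParams:
    return ModelParams(**(d or {}))


def schedule_from_dict(items: list[dict]) -> PhaseSchedule:
    phases = [
        Phase(p["name"], float(p["duration"]), dict(p.get("overrides", {})))
        for p in items
    ]
    return PhaseSchedule(phases)


def save_trajectory(traj, out_dir: str | Path, stem: str = "trajectory") -> dict[str, Path]:
    """Write the morphometric time series (CSV) and sampled boundary
    polygons (JSON) of one simulation run; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}_metrics.csv"
    traj.metrics.to_csv(csv_path, index=False)
    poly_path = out_dir / f"{stem}_boundaries.json"
    payload = {
        "seed": traj.seed,
        "phase_bounds": {k: list(v) for k, v in traj.phase_bounds.items()},
        "times": [float(t) for t in traj.times],
        "boundaries": [s.vertices.round(6).tolist() for s in traj.states],
    }
    poly_path.write_text(json.dumps(payload))
    return {"metrics": csv_path, "boundaries": poly_path}
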