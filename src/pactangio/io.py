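"""File I/O: float TIFF images with JSON sidecars, HDF5 channel data, CSV.

Images travel as 32-bit float TIFF with a ``<name>.json`` sidecar carrying
pixel spacing, provenance, and any masks (run-length encoded).  Channel
data uses HDF5 with geometry stored as attributes.  Skeletons export as CSV
polylines (segment_id, x_mm, y_mm).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .preprocess import MapImage
from .simulator import ChannelData, RingArrayGeometry
from .vesselmetrics import SkeletonGraph

__all__ = [
    "rle_encode",
    "rle_decode",
    "write_map_tiff",
    "read_map_tiff",
    "write_channel_h5",
    "read_channel_h5",
    "write_skeleton_csv",
]


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (C order, starting with False runs)."""
    flat = np.asarray(mask, bool).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "runs": []}
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:  # convention: runs alternate starting with a False run
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(payload: dict) -> np.ndarray:
    shape = tuple(payload["shape"])
    runs = payload["runs"]
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            out[pos:pos + r] = True
        pos += r
        val = not val
    return out.reshape(shape)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_map_tiff(path, image: MapImage, masks: dict | None = None,
                   extra: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    meta = {
        "pixel_size_mm": image.pixel_size_mm,
        "provenance": image.provenance,
        "masks": {k: rle_encode(v) for k, v in (masks or {}).items()},
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_map_tiff(path) -> tuple[MapImage, dict]:
    path = Path(path)
    pixels = tifffile.imread(path).astype(float)
    meta = {}
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
    image = MapImage(pixels, float(meta.get("pixel_size_mm", 1.0)),
                     list(meta.get("provenance", [])))
    masks = {k: rle_decode(v) for k, v in meta.get("masks", {}).items()}
    return image, {**meta, "masks": masks}


def write_channel_h5(path, data: ChannelData) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("traces", data=data.traces.astype(np.float32))
        ds.attrs["dt_us"] = data.dt_us
        g = f.create_group("geometry")
        for k, v in dataclasses.asdict(data.geometry).items():
            g.attrs[k] = "none" if v is None else v


def read_channel_h5(path) -> ChannelData:
    with h5py.File(path, "r") as f:
        traces = f["traces"][()].astype(float)
        dt = float(f["traces"].attrs["dt_us"])
        attrs = dict(f["geometry"].attrs)
    if attrs.get("fractional_bandwidth") == "none":
        attrs["fractional_bandwidth"] = None
    geom = RingArrayGeometry(**{k: (v if isinstance(v, (str, type(None))) else float(v))
                                if k == "fractional_bandwidth"
                                else (int(v) if k == "n_elements" else float(v))
                                for k, v in attrs.items()})
    return ChannelData(traces, dt, geom)


def write_skeleton_csv(path, graph: SkeletonGraph) -> None:
    """Export segment polylines as CSV rows (segment_id, x_mm, y_mm)."""
    h = graph.pixel_size_mm
    lines = ["segment_id,x_mm,y_mm"]
    for seg_id, coords in sorted(graph.segments.items()):
        for i, j in coords:
            lines.append(f"{seg_id},{j * h:.4f},{i * h:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
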