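"""Reading and writing height maps, event tables and summaries.

Height maps travel as single-channel 32-bit float TIFF (μm) or plain
CSV grids, with pixel size and provenance in a JSON sidecar named
``<stem>.meta.json``.  Event tables and measurements are CSV via pandas.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quantify import CohortSummary, EventMeasurement
from .simulate import ResorptionEvent
from .surface import HeightMap

__all__ = [
    "write_heightmap",
    "read_heightmap",
    "events_to_dataframe",
    "measurements_to_dataframe",
    "summary_to_dict",
    "write_summary",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_heightmap(surface: HeightMap, path: str | Path, metadata: dict | None = None) -> Path:
    """Write a height map as float32 TIFF (.tif) or CSV grid (.csv)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, surface.heights.astype(np.float32))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, surface.heights, delimiter=",", fmt="%.6g")
    else:
        raise ValueError(f"unsupported height-map format: {path.suffix}")
    meta = {"pixel_size_um": surface.pixel_size, "units": "um"}
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_heightmap(path: str | Path) -> HeightMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = np.asarray(tifffile.imread(path), dtype=float)
    elif path.suffix.lower() == ".csv":
        heights = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        raise ValueError(f"unsupported height-map format: {path.suffix}")
    pixel_size = 1.0
    sidecar = _sidecar(path)
    if sidecar.exists():
        pixel_size = float(json.loads(sidecar.read_text()).get("pixel_size_um", 1.0))
    return HeightMap(heights, pixel_size)


def events_to_dataframe(events: list[ResorptionEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "type": e.kind,
                "center_x_um": e.x,
                "center_y_um": e.y,
                "donor_id": e.donor_id,
                "length_um": e.length,
                "width_um": e.width,
                "depth_um": e.depth,
                "d_max_um": e.d_max,
                "n_cycles": len(e.cycles),
                "realized_volume_um3": e.realized_volume_um3,
            }
        )
    return pd.DataFrame(rows)


def measurements_to_dataframe(measurements: list[EventMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "label": m.label_id,
                "area_um2": m.area,
                "length_um": m.length,
                "width_um": m.width,
                "max_depth_um": m.max_depth,
                "quantized_depth_um": m.quantized_depth,
                "volume_um3": m.volume,
                "centroid_x_um": m.centroid[0],
                "centroid_y_um": m.centroid[1],
                "touches_edge": m.touches_edge,
            }
        )
    return pd.DataFrame(rows)


def summary_to_dict(summary: CohortSummary) -> dict:
    d = dataclasses.asdict(summary)
    d["donor_ids"] = list(d["donor_ids"])
    return d


def write_summary(summary: CohortSummary, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary_to_dict(summary), indent=2))
    return path
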