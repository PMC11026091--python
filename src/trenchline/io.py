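"""Readers, writers and naming conventions tying the pipeline stages together.

Raw experiments arrive as single-page TIFF series whose filenames encode
the field of view, time point and imaging plane; intermediate products
(channel stacks, subtracted stacks, label masks) are multi-page TIFFs;
tracked lineages are exported as a flat CSV (one row per cell-frame plus a
per-cell summary row) and a nested, schema-versioned JSON that round-trips
the full record forest.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .track import CellRecord, RegionFeature

__all__ = [
    "FrameKey",
    "DEFAULT_PATTERN",
    "parse_frame_key",
    "format_frame_key",
    "load_tiff_series",
    "export_cells",
    "import_cells",
]

#: matches e.g. ``exp_t0003_xy12_c1.tif``
DEFAULT_PATTERN = r"^(?P<prefix>.*)_t(?P<time>\d+)_xy(?P<fov>\d+)_c(?P<plane>\d+)\.tiff?$"

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class FrameKey:
    fov: int
    time: int
    plane: int


def parse_frame_key(filename: str | Path, pattern: str = DEFAULT_PATTERN) -> FrameKey:
    """Extract (fov, time, plane) from a raw TIFF filename.

    ``pattern`` is a regex with named groups ``fov``, ``time`` and
    ``plane``; the default accepts names like ``exp_t0003_xy12_c1.tif``.
    """
    name = Path(filename).name
    m = re.match(pattern, name)
    if m is None:
        raise ValueError(f"filename {name!r} does not match pattern {pattern!r}")
    return FrameKey(fov=int(m["fov"]), time=int(m["time"]), plane=int(m["plane"]))


def format_frame_key(key: FrameKey, prefix: str = "exp") -> str:
    """Inverse of :func:`parse_frame_key` for the default pattern."""
    return f"{prefix}_t{key.time:04d}_xy{key.fov:02d}_c{key.plane}.tif"


def load_tiff_series(directory: str | Path,
                     pattern: str = DEFAULT_PATTERN) -> dict[tuple[int, int], np.ndarray]:
    """Load a raw single-page TIFF series into per-(fov, plane) stacks.

    Returns ``{(fov, plane): (T, H, W) array}`` with frames ordered by
    time; missing time points raise.
    """
    directory = Path(directory)
    frames: dict[tuple[int, int], dict[int, np.ndarray]] = {}
    for path in sorted(directory.iterdir()):
        if not path.suffix.lower() in (".tif", ".tiff"):
            continue
        key = parse_frame_key(path, pattern)
        frames.setdefault((key.fov, key.plane), {})[key.time] = tifffile.imread(path)
    out = {}
    for fp, by_time in frames.items():
        times = sorted(by_time)
        if times != list(range(times[0], times[0] + len(times))):
            raise ValueError(f"missing time points for fov/plane {fp}: have {times}")
        out[fp] = np.stack([by_time[t] for t in times])
    return out


def _cell_to_dict(cell: CellRecord) -> dict:
    d = {
        "id": cell.id, "fov": cell.fov, "channel": cell.channel,
        "birth_frame": cell.birth_frame, "rank": cell.rank,
        "parent": cell.parent, "daughters": list(cell.daughters) if cell.daughters else None,
        "division_frame": cell.division_frame, "status": cell.status,
        "interpolated_frames": cell.interpolated_frames,
        "features": [dataclasses.asdict(f) for f in cell.features],
    }
    return d


def _cell_from_dict(d: dict) -> CellRecord:
    cell = CellRecord(
        id=d["id"], fov=d["fov"], channel=d["channel"],
        birth_frame=d["birth_frame"], rank=d["rank"], parent=d["parent"],
        daughters=tuple(d["daughters"]) if d["daughters"] else None,
        division_frame=d["division_frame"], status=d["status"],
        interpolated_frames=list(d.get("interpolated_frames", [])),
    )
    cell.features = [RegionFeature(**f) for f in d["features"]]
    return cell


def export_cells(cells: list[CellRecord], csv_path: str | Path | None = None,
                 json_path: str | Path | None = None) -> pd.DataFrame:
    """Export a record forest as flat CSV and/or nested JSON.

    The CSV holds one row per cell-frame observation; per-cell summary
    columns (birth/division frame, parent, status) are repeated on each
    row so the file is self-contained.  Ordering is deterministic (by cell
    id, then frame).  Returns the flat table.
    """
    cells = sorted(cells, key=lambda c: c.id)
    rows = []
    for cell in cells:
        for f in cell.features:
            rows.append({
                "cell_id": cell.id, "fov": cell.fov, "channel": cell.channel,
                "frame": f.frame, "label": f.label,
                "centroid_y_px": f.centroid_y, "centroid_x_px": f.centroid_x,
                "length_px": f.length, "width_px": f.width,
                "area_px2": f.area, "volume_px3": f.volume,
                "birth_frame": cell.birth_frame,
                "division_frame": -1 if cell.division_frame is None else cell.division_frame,
                "parent": cell.parent or "",
                "status": cell.status,
            })
    columns = ["cell_id", "fov", "channel", "frame", "label", "centroid_y_px",
               "centroid_x_px", "length_px", "width_px", "area_px2", "volume_px3",
               "birth_frame", "division_frame", "parent", "status"]
    table = pd.DataFrame(rows, columns=columns)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if json_path is not None:
        doc = {"schema_version": SCHEMA_VERSION,
               "cells": [_cell_to_dict(c) for c in cells]}
        Path(json_path).write_text(json.dumps(doc, indent=1))
    return table


def import_cells(json_path: str | Path) -> list[CellRecord]:
    """Round-trip inverse of the JSON export."""
    doc = json.loads(Path(json_path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {doc.get('schema_version')}")
    return [_cell_from_dict(d) for d in doc["cells"]]


def write_label_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a labeled-mask stack as a 16-bit multi-page TIFF.

    Labels are stored 16-bit: a long channel history can exceed 255
    distinct cells, which an 8-bit stack could not represent without
    per-stack relabeling.
    """
    stack = np.asarray(stack)
    if stack.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values exceed 16-bit range")
    tifffile.imwrite(path, stack.astype(np.uint16))


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
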