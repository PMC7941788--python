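"""Readers and writers for the pipeline's text formats.

Everything is plain text so runs diff cleanly: CSV for tabular data
(geometry, count panels, excess, posterior summaries), JSON for summaries
and manifests, and ESRI ASCII grid (.asc) for the interpolated raster.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from wildfire_excess.surface import GridSurface

__all__ = [
    "read_count_panel",
    "write_count_panel",
    "read_geometry",
    "write_geometry",
    "write_excess",
    "read_excess",
    "write_asc_grid",
    "read_asc_grid",
    "write_json",
]


def read_count_panel(path) -> pd.DataFrame:
    """Read and validate a long-format count panel CSV (unit_id, date, count).

    Raises ValueError naming the offending rows for malformed or non-ISO
    dates, non-integer or negative counts, and duplicate (unit, date) cells.
    """
    df = pd.read_csv(path, dtype={"unit_id": str, "count": str})
    need = {"unit_id", "date", "count"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}, got {list(df.columns)}")

    dates, counts = [], []
    for row, (d, c) in enumerate(zip(df["date"], df["count"]), start=2):  # 1-based + header
        try:
            dates.append(dt.date.fromisoformat(str(d)))
        except ValueError:
            raise ValueError(f"{path} row {row}: malformed ISO-8601 date {d!r}") from None
        try:
            ci = int(str(c))
        except ValueError:
            raise ValueError(f"{path} row {row}: count {c!r} is not an integer") from None
        if ci < 0:
            raise ValueError(f"{path} row {row}: negative count {ci}")
        counts.append(ci)
    df = pd.DataFrame({"unit_id": df["unit_id"], "date": dates, "count": counts})
    dup = df.duplicated(subset=["unit_id", "date"])
    if dup.any():
        rows = (np.flatnonzero(dup) + 2).tolist()
        raise ValueError(f"{path}: duplicate (unit_id, date) rows at lines {rows}")
    return df


def write_count_panel(panel: pd.DataFrame, path) -> None:
    out = panel.copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False)


def read_geometry(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str})
    need = {"unit_id", "x_km", "y_km"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    if df["unit_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate unit_ids")
    if not np.isfinite(df[["x_km", "y_km"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinates")
    return df


def write_geometry(geometry: pd.DataFrame, path) -> None:
    geometry.to_csv(path, index=False)


def write_excess(excess: pd.DataFrame, path) -> None:
    out = excess.copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, index=False)


def read_excess(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str})
    df["date"] = [dt.date.fromisoformat(str(d)) for d in df["date"]]
    return df


def write_asc_grid(surface: GridSurface, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid; rows written north-to-south as the format requires."""
    n = surface.grid_n
    cx, cy = surface.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {n}\n")
        fh.write(f"nrows {n}\n")
        fh.write(f"xllcorner {surface.x_min:.6f}\n")
        fh.write(f"yllcorner {surface.y_min:.6f}\n")
        fh.write(f"cellsize {cx:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in surface.values[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_asc_grid(path) -> GridSurface:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            k, v = fh.readline().split()
            hdr[k.lower()] = float(v)
        vals = np.loadtxt(fh)
    n = int(hdr["nrows"])
    cell = hdr["cellsize"]
    return GridSurface(
        vals[::-1].copy(),
        hdr["xllcorner"],
        hdr["yllcorner"],
        hdr["xllcorner"] + cell * int(hdr["ncols"]),
        hdr["yllcorner"] + cell * n,
    )


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (dt.date, dt.datetime)):
            return o.isoformat()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
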