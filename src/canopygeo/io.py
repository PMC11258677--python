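"""Readers/writers for footprint tables and grids, plus systematic thinning.

Footprint tables are delimited text with the fixed column schema
(id, x, y, nfcc, seven segment covariates, elevation, slope, aspect) or
GeoJSON point collections; grids go to ESRI ASCII rasters (node-registered,
lower-left origin).  Coordinates are planar projected meters throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridGeometry
from .synthetic import FOOTPRINT_COLUMNS

__all__ = [
    "systematic_sample",
    "read_footprints",
    "write_footprints",
    "write_footprints_geojson",
    "read_footprints_geojson",
    "write_esri_ascii",
    "read_esri_ascii",
]


def systematic_sample(records, interval: int, offset: int = 0):
    """Keep every ``interval``-th record starting at position ``offset``.

    Positions are 0-based: the kept positions are offset, offset+interval,
    offset+2*interval, ... so the kept count is ceil((n - offset)/interval).
    Thinning 11,060 ordered records at interval 10 keeps 1,106.
    """
    if interval < 1:
        raise ValueError("sampling interval must be >= 1")
    if not 0 <= offset < interval:
        raise ValueError("offset must satisfy 0 <= offset < interval")
    if isinstance(records, pd.DataFrame):
        return records.iloc[offset::interval].reset_index(drop=True)
    arr = np.asarray(records)
    return arr[offset::interval]


def write_footprints(frame: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a footprint table as delimited text with the canonical schema."""
    _check_schema(frame)
    frame = frame[list(FOOTPRINT_COLUMNS)]
    frame.to_csv(path, sep=sep, index=False)


def read_footprints(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a delimited footprint table.

    Raises with the missing column names if the schema is incomplete and
    with 1-based line numbers for rows that fail numeric parsing or the
    cover-bounds invariant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=sep)
    _check_schema(frame)
    numeric = [c for c in FOOTPRINT_COLUMNS if c != "id"]
    bad_lines: list[int] = []
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna() | frame[col].isna()
        bad_lines.extend((frame.index[bad] + 2).tolist())  # +1 header, +1 1-based
        frame[col] = coerced
    out_of_range = (frame["nfcc"] < 0) | (frame["nfcc"] > 1)
    bad_lines.extend((frame.index[out_of_range.fillna(False)] + 2).tolist())
    if bad_lines:
        raise ValueError(
            f"malformed footprint rows at line(s) {sorted(set(bad_lines))} in {path}"
        )
    frame["id"] = frame["id"].astype(int)
    return frame[list(FOOTPRINT_COLUMNS)]


def _check_schema(frame: pd.DataFrame) -> None:
    missing = [c for c in FOOTPRINT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"footprint table is missing column(s): {', '.join(missing)}")


def write_footprints_geojson(frame: pd.DataFrame, path) -> None:
    """Write footprints as a GeoJSON FeatureCollection of points.

    Coordinates are the planar projected x/y in meters; all remaining
    schema columns become feature properties.
    """
    _check_schema(frame)
    features = []
    prop_cols = [c for c in FOOTPRINT_COLUMNS if c not in ("x", "y")]
    for _, row in frame.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["x"]), float(row["y"])]},
            "properties": {c: (int(row[c]) if c in ("id",) else float(row[c]))
                           for c in prop_cols},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_footprints_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    rows = []
    for feat in doc["features"]:
        x, y = feat["geometry"]["coordinates"]
        rows.append({"x": x, "y": y, **feat["properties"]})
    frame = pd.DataFrame(rows)
    _check_schema(frame)
    frame["id"] = frame["id"].astype(int)
    return frame[list(FOOTPRINT_COLUMNS)]


def write_esri_ascii(grid, geometry: GridGeometry, path, nodata: float = -9999.0) -> None:
    """Write a 2-D surface as an ESRI ASCII raster (node-registered).

    Our grids store row 0 at ymin; the format writes the top row first, so
    rows are flipped on output.  NaNs become the nodata value.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != geometry.shape:
        raise ValueError("grid shape does not match geometry")
    out = np.where(np.isfinite(grid), grid, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {geometry.ncols}\n")
        fh.write(f"nrows {geometry.nrows}\n")
        fh.write(f"xllcenter {geometry.xmin!r}\n")
        fh.write(f"yllcenter {geometry.ymin!r}\n")
        fh.write(f"cellsize {geometry.cell!r}\n")
        fh.write(f"nodata_value {nodata!r}\n")
        for row in out[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_esri_ascii(path) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII raster back to (surface, geometry); nodata -> NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcenter", "yllcenter",
                       "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    cell = header["cellsize"]
    if "xllcenter" in header:
        xmin, ymin = header["xllcenter"], header["yllcenter"]
    else:  # corner-registered input: shift to node registration
        xmin = header["xllcorner"] + cell / 2.0
        ymin = header["yllcorner"] + cell / 2.0
    geom = GridGeometry(xmin, ymin, cell, int(header["nrows"]), int(header["ncols"]))
    grid = np.asarray(rows, dtype=float)[::-1]
    if grid.shape != geom.shape:
        raise ValueError(f"raster body {grid.shape} does not match header {geom.shape}")
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    return grid, geom
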