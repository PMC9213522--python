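"""Raster and vector I/O and the on-disk conventions shared by the pipeline.

Rasters are monthly land/water/missing classification grids.  A stack is
stored either as a directory of single-band TIFFs named ``YYYY_MM.tif`` or
as one multi-page TIFF whose pages are chronological.  Plain TIFF carries no
georeferencing, so the affine transform and CRS identifier live in a JSON
sidecar (``<stem>.georef.json`` next to the raster, or ``georef.json``
inside a stack directory).

Coordinate conventions: row-major 0-based pixel indices; the affine
transform maps the *upper-left corner* of cell (row, col) to world
coordinates, GDAL-style ``(x0, dx, 0, y0, 0, dy)`` with dy typically
negative for north-up grids.  Polygons are traced on cell edges.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

# Ternary label codes used everywhere in the package.
LAND = 0
WATER = 1
MISSING = 2

#: Area of one 30 m x 30 m Landsat cell in square kilometres.
PIXEL_AREA_KM2 = 0.0009

#: Fixed column order of the per-lake monthly area CSV.
AREA_TABLE_COLUMNS = [
    "lake_id",
    "year",
    "month",
    "water_pixel_count",
    "area_km2",
    "pct_imputed",
    "pct_corrected",
    "all_missing_flag",
]


@dataclass(frozen=True)
class Georef:
    """Affine georeference: GDAL-style transform plus a CRS identifier.

    ``transform`` is ``(x0, dx, rx, y0, ry, dy)``; world coordinates of the
    upper-left corner of cell (row, col) are
    ``x = x0 + col*dx + row*rx`` and ``y = y0 + col*ry + row*dy``.
    """

    transform: tuple[float, float, float, float, float, float]
    crs: str | None = None

    def pixel_polygon(self, row: int, col: int):
        """Axis-aligned world-coordinate square of one cell (rx=ry=0 only)."""
        x0, dx, rx, y0, ry, dy = self.transform
        if rx != 0 or ry != 0:
            raise ValueError("rotated transforms are not supported for polygonization")
        x = x0 + col * dx
        y = y0 + row * dy
        return box(min(x, x + dx), min(y, y + dy), max(x, x + dx), max(y, y + dy))

    def to_dict(self) -> dict:
        return {"transform": list(self.transform), "crs": self.crs}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Georef":
        return cls(transform=tuple(float(v) for v in d["transform"]), crs=d.get("crs"))

    @classmethod
    def identity(cls, pixel_size: float = 1.0) -> "Georef":
        return cls(transform=(0.0, pixel_size, 0.0, 0.0, 0.0, -pixel_size), crs=None)


@dataclass
class TernaryStack:
    """Monthly land/water/missing stack: the pipeline's central input.

    labels : (T, R, C) uint8 array with codes LAND=0, WATER=1, MISSING=2
    timestamps : strictly increasing (year, month) pairs, one per frame
    georef : optional affine transform + CRS
    pixel_area_km2 : area of one cell in square kilometres
    """

    labels: np.ndarray
    timestamps: list[tuple[int, int]]
    georef: Georef | None = None
    pixel_area_km2: float = PIXEL_AREA_KM2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3-D (T,R,C), got shape {self.labels.shape}")
        bad = ~np.isin(self.labels, (LAND, WATER, MISSING))
        if bad.any():
            vals = np.unique(self.labels[bad])
            raise ValueError(f"labels contain codes outside {{0,1,2}}: {vals.tolist()}")
        self.labels = self.labels.astype(np.uint8, copy=False)
        self.timestamps = [(int(y), int(m)) for y, m in self.timestamps]
        if len(self.timestamps) != self.labels.shape[0]:
            raise ValueError(
                f"{len(self.timestamps)} timestamps for {self.labels.shape[0]} frames"
            )
        if any(b <= a for a, b in zip(self.timestamps, self.timestamps[1:])):
            raise ValueError("timestamps must be strictly increasing")
        if not self.pixel_area_km2 > 0:
            raise ValueError("pixel_area_km2 must be positive")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape[1:]


@dataclass
class OccurrenceLayer:
    """Per-pixel percentage of observed months classified as water (0-100).

    NaN marks cells with no valid observation in any month.
    """

    percent: np.ndarray
    georef: Georef | None = None

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        if self.percent.ndim != 2:
            raise ValueError("percent must be 2-D")
        finite = self.percent[np.isfinite(self.percent)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("occurrence percentages must lie in [0, 100]")


_FNAME_RE = re.compile(r"(\d{4})[_-](\d{1,2})")


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "georef.json"
    return path.with_suffix(path.suffix + ".georef.json")


def _read_sidecar(path: Path) -> tuple[Georef | None, list[tuple[int, int]] | None, float | None]:
    sc = _sidecar_path(path)
    if not sc.exists():
        return None, None, None
    meta = json.loads(sc.read_text())
    georef = Georef.from_dict(meta["georef"]) if meta.get("georef") else None
    ts = [tuple(t) for t in meta["timestamps"]] if meta.get("timestamps") else None
    return georef, ts, meta.get("pixel_area_km2")


def read_stack(
    path: str | Path,
    code_map: Mapping[int, int] | None = None,
    timestamps: Sequence[tuple[int, int]] | None = None,
) -> TernaryStack:
    """Read a ternary stack from a directory of TIFFs or a multi-page TIFF.

    ``code_map`` maps raster values to the ternary codes; by default the
    identity mapping {0: LAND, 1: WATER, 2: MISSING}.  Raster values absent
    from the mapping raise rather than being coerced.  Timestamps come from,
    in order of precedence: the ``timestamps`` argument, the JSON sidecar,
    ``YYYY_MM`` filenames (directory input), or a synthetic monthly axis
    starting 2000-01.
    """
    path = Path(path)
    code_map = dict(code_map) if code_map is not None else {0: LAND, 1: WATER, 2: MISSING}
    georef, sidecar_ts, pix_area = _read_sidecar(path)

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in {path}")
        frames = [tifffile.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"monthly rasters disagree in shape: {sorted(shapes)}")
        raw = np.stack(frames)
        if timestamps is None and sidecar_ts is None:
            parsed = [_FNAME_RE.search(f.stem) for f in files]
            if all(parsed):
                sidecar_ts = [(int(m.group(1)), int(m.group(2))) for m in parsed]  # type: ignore[union-attr]
    elif path.exists():
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
    else:
        raise FileNotFoundError(path)

    ts = list(timestamps) if timestamps is not None else sidecar_ts
    if ts is None:
        ts = [(2000 + i // 12, 1 + i % 12) for i in range(raw.shape[0])]

    values = np.unique(raw)
    unknown = [int(v) for v in values if int(v) not in code_map]
    if unknown:
        raise ValueError(f"raster contains unmapped values {unknown}; supply a code_map")
    lut = np.full(int(values.max()) + 1, 255, dtype=np.uint8)
    for src, dst in code_map.items():
        if src <= values.max():
            lut[src] = dst
    labels = lut[raw]

    return TernaryStack(
        labels=labels,
        timestamps=ts,
        georef=georef,
        pixel_area_km2=pix_area if pix_area is not None else PIXEL_AREA_KM2,
    )


def write_stack(stack: TernaryStack, path: str | Path, layout: str = "directory") -> Path:
    """Write a stack as per-month TIFFs in a directory (default) or one
    multi-page TIFF, plus the JSON georeference/timestamp sidecar."""
    path = Path(path)
    if layout == "directory":
        path.mkdir(parents=True, exist_ok=True)
        for frame, (year, month) in zip(stack.labels, stack.timestamps):
            tifffile.imwrite(path / f"{year:04d}_{month:02d}.tif", frame)
    elif layout == "multiband":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack.labels, photometric="minisblack")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    meta = {
        "georef": stack.georef.to_dict() if stack.georef else None,
        "timestamps": [list(t) for t in stack.timestamps],
        "pixel_area_km2": stack.pixel_area_km2,
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_occurrence(path: str | Path) -> OccurrenceLayer:
    """Read a single-band occurrence raster (float percent; NaN = never observed)."""
    path = Path(path)
    georef, _, _ = _read_sidecar(path)
    arr = tifffile.imread(path)
    return OccurrenceLayer(percent=np.asarray(arr, dtype=float), georef=georef)


def write_occurrence(layer: OccurrenceLayer, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, layer.percent.astype(np.float32))
    if layer.georef is not None:
        _sidecar_path(path).write_text(json.dumps({"georef": layer.georef.to_dict()}))
    return path


# ---------------------------------------------------------------------------
# Vector output
# ---------------------------------------------------------------------------

def mask_to_polygon(mask: np.ndarray, georef: Georef | None = None):
    """Trace a pixel set as one (possibly multi-part) cell-edge polygon.

    Without a georeference, pixel-index coordinates are used with the
    identity transform (x=col, y=-row, north-up).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot polygonize an empty mask")
    gr = georef if georef is not None else Georef.identity()
    rows, cols = np.nonzero(mask)
    geom = unary_union([gr.pixel_polygon(int(r), int(c)) for r, c in zip(rows, cols)])
    if not geom.is_valid:
        geom = geom.buffer(0)
        if not geom.is_valid:
            raise ValueError("polygonization produced an invalid geometry")
    return geom


def write_polygons(records: Iterable, path: str | Path, format: str = "geojson") -> Path:
    """Write lake records as a GeoJSON FeatureCollection, one feature per lake.

    Each record must expose ``lake_id`` and a pixel ``mask`` (plus optional
    score/flag attributes); a lake's disjoint parts become one multi-part
    polygon keyed by lake_id.  Attribute values round-trip losslessly
    through :func:`read_polygons`.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    if format not in ("geojson",):
        raise ValueError(
            f"format {format!r} unsupported: only GeoJSON output is available"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for rec in records:
        geom = mask_to_polygon(rec.mask, getattr(rec, "georef", None))
        props = {
            "lake_id": int(rec.lake_id),
            "n_pixels": int(rec.n_pixels),
            "area_km2": float(rec.area_km2),
            "erosion_count": int(rec.erosion_count) if rec.erosion_count is not None else None,
            "morph_score": float(rec.morph_score) if rec.morph_score is not None else None,
            "river_flag": bool(rec.river_flag) if rec.river_flag is not None else None,
            "line_overlap_flag": bool(rec.line_overlap_flag)
            if getattr(rec, "line_overlap_flag", None) is not None
            else None,
            "cs": float(rec.cs) if getattr(rec, "cs", None) is not None else None,
            "es": int(rec.es) if getattr(rec, "es", None) is not None else None,
            "reliable_flag": bool(rec.reliable_flag)
            if getattr(rec, "reliable_flag", None) is not None
            else None,
        }
        features.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_polygons(path: str | Path) -> list[dict]:
    """Read back a GeoJSON written by :func:`write_polygons`.

    Returns a list of dicts with ``geometry`` (shapely) and the attributes.
    """
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        d = dict(feat["properties"])
        d["geometry"] = shape(feat["geometry"])
        out.append(d)
    return out


# ---------------------------------------------------------------------------
# Area tables
# ---------------------------------------------------------------------------

def validate_area_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and internal consistency of a monthly area table."""
    missing = [c for c in AREA_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"area table missing columns {missing}")
    t = table[AREA_TABLE_COLUMNS]
    for col in ("pct_imputed", "pct_corrected"):
        v = t[col].to_numpy(dtype=float)
        if ((v < 0) | (v > 100)).any():
            raise ValueError(f"{col} outside [0, 100]")
    return t


def write_area_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the monthly area table as CSV with full float precision."""
    t = validate_area_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t.to_csv(path, index=False, float_format="%.17g")
    return path


def read_area_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["all_missing_flag"] = df["all_missing_flag"].astype(bool)
    return validate_area_table(df)
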