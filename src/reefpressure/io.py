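"""Readers and writers for the package's on-disk formats.

Rasters are stored as single-band float64 TIFFs (via :mod:`tifffile`) with the
grid geometry embedded as a JSON document in the TIFF description tag, so a
raster file round-trips self-contained. Polygon layers are GeoJSON
FeatureCollections written with deterministic key order and float formatting,
so identical inputs produce byte-identical files. Tables are plain CSV through
pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import Grid

__all__ = [
    "write_raster",
    "read_raster",
    "write_geojson",
    "read_geojson",
]


def write_raster(path: str | Path, array: np.ndarray, grid: Grid) -> None:
    """Write a 2-D float raster with its grid metadata to a TIFF file."""
    arr = np.asarray(array, dtype=np.float64)
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} != grid shape {grid.shape}")
    meta = json.dumps(grid.to_dict(), sort_keys=True)
    tifffile.imwrite(str(path), arr, description=meta)


def read_raster(path: str | Path) -> tuple[np.ndarray, Grid]:
    """Read a raster written by :func:`write_raster`; returns (array, grid)."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = page.asarray().astype(np.float64)
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: missing grid metadata in TIFF description")
        grid = Grid.from_dict(json.loads(desc.value))
    return arr, grid


def _round_coords(obj, ndigits: int = 6):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(v, ndigits) for v in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def write_geojson(
    path: str | Path,
    geometries: Iterable[BaseGeometry],
    properties: Iterable[Mapping] | None = None,
    crs: str | None = None,
) -> None:
    """Write geometries (+ per-feature properties) as a GeoJSON collection.

    Coordinates are rounded to 1e-6 plane units and keys sorted, making the
    output deterministic at file level for identical inputs.
    """
    geometries = list(geometries)
    props = list(properties) if properties is not None else [{} for _ in geometries]
    if len(props) != len(geometries):
        raise ValueError("properties length does not match geometries")
    features = []
    for geom, prop in zip(geometries, props):
        gj = _round_coords(mapping(geom))
        features.append({"type": "Feature", "geometry": gj, "properties": dict(prop)})
    doc = {"type": "FeatureCollection", "features": features}
    if crs is not None:
        doc["crs_note"] = crs
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n")


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    """Read a GeoJSON FeatureCollection; returns (geometries, properties)."""
    doc = json.loads(Path(path).read_text())
    geoms, props = [], []
    for feat in doc["features"]:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties", {}))
    return geoms, props
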