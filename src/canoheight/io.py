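"""Readers and writers for point clouds, rasters and crown polygons.

Formats: LAS 1.2-1.4 (optional ``laspy`` backend), whitespace/CSV xyz
text, ESRI ASCII grid, GeoTIFF (via ``tifffile`` with GeoTIFF pixel-scale
and tie-point tags), and GeoJSON crowns.  Readers never silently drop
rows: every input row is parsed or an error names the offending line.
"""

from __future__ import annotations

import json
import os

import numpy as np
from shapely.geometry import shape, mapping, Polygon

from .core import PointCloud, RasterGrid, CrownSet, UNCLASSIFIED, GROUND, VEGETATION

NODATA = -9999.0

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".las", ".laz"):
        return "las"
    return "xyz-text"


def read_point_cloud(path: str, format: str | None = None) -> PointCloud:
    """Read a point cloud from LAS or xyz text.

    xyz text columns are ``x y z [return_number] [classification]``,
    whitespace- or comma-separated; lines starting with ``#`` are skipped.
    Missing return numbers default to 1, missing classes to unclassified.
    """
    fmt = _detect_format(path, format)
    if fmt == "las":
        return _read_las(path)
    if fmt == "xyz-text":
        return _read_xyz_text(path)
    raise ValueError(f"unknown point-cloud format: {fmt!r}")


def _read_xyz_text(path: str) -> PointCloud:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns, "
                                 f"got {len(parts)}")
            try:
                vals = [float(p) for p in parts[:5]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            rows.append(vals + [np.nan] * (5 - len(vals)))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    rn = np.where(np.isnan(arr[:, 3]), 1, arr[:, 3]).astype(int)
    cls = np.where(np.isnan(arr[:, 4]), UNCLASSIFIED, arr[:, 4]).astype(int)
    return PointCloud(arr[:, 0], arr[:, 1], arr[:, 2], rn, cls)


def _read_las(path: str) -> PointCloud:
    try:
        import laspy
    except ImportError:
        raise ImportError(
            "LAS support requires the optional 'laspy' backend "
            "(pip install canoheight[las]); xyz-text input needs no extras."
        ) from None
    las = laspy.read(path)
    cls = np.asarray(las.classification, dtype=int)
    out = np.full(cls.shape, UNCLASSIFIED, dtype=int)
    out[cls == 2] = GROUND
    out[np.isin(cls, (3, 4, 5))] = VEGETATION
    return PointCloud(np.asarray(las.x), np.asarray(las.y), np.asarray(las.z),
                      np.asarray(las.return_number, dtype=int), out)


def write_point_cloud(cloud: PointCloud, path: str) -> None:
    """Write a cloud as xyz text (x y z return classification)."""
    data = np.column_stack([cloud.x, cloud.y, cloud.z,
                            cloud.return_number, cloud.classification])
    header = "x y z return_number classification"
    np.savetxt(path, data, fmt="%.3f %.3f %.3f %d %d",
               header=header, comments="# ")


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str, format: str | None = None) -> None:
    """Write a grid as ESRI ASCII (.asc) or GeoTIFF (.tif)."""
    fmt = format or ("geotiff" if os.path.splitext(path)[1].lower()
                     in (".tif", ".tiff") else "esri-ascii")
    if fmt == "esri-ascii":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown raster format: {fmt!r}")


def read_raster(path: str, format: str | None = None) -> RasterGrid:
    fmt = format or ("geotiff" if os.path.splitext(path)[1].lower()
                     in (".tif", ".tiff") else "esri-ascii")
    if fmt == "esri-ascii":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format: {fmt!r}")


def _write_ascii(grid: RasterGrid, path: str) -> None:
    vals = np.where(np.isnan(grid.values), NODATA, grid.values)
    x0, y0 = grid.origin
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcenter {x0:.6f}\n")
        fh.write(f"yllcenter {y0:.6f}\n")
        fh.write(f"cellsize {grid.cell:.6f}\n")
        fh.write(f"nodata_value {NODATA}\n")
        # ESRI ASCII stores rows north-to-south
        np.savetxt(fh, vals[::-1], fmt="%.6f")


def _read_ascii(path: str) -> RasterGrid:
    hdr = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcenter", "yllcenter",
                "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            hdr[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    vals = np.loadtxt(lines[i:], dtype=float)
    vals = np.atleast_2d(vals)[::-1].copy()
    cell = hdr["cellsize"]
    if "xllcenter" in hdr:
        x0, y0 = hdr["xllcenter"], hdr["yllcenter"]
    else:
        x0, y0 = hdr["xllcorner"] + cell / 2, hdr["yllcorner"] + cell / 2
    nodata = hdr.get("nodata_value", NODATA)
    vals[vals == nodata] = np.nan
    return RasterGrid((x0, y0), cell, vals)


def _write_geotiff(grid: RasterGrid, path: str) -> None:
    import tifffile
    x0, y0 = grid.origin
    cell = grid.cell
    # tiepoint references the upper-left corner of the top-left pixel
    top = y0 + (grid.nrows - 1) * cell + cell / 2
    left = x0 - cell / 2
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cell, cell, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, left, top, 0.0)),
        (_GDAL_NODATA, "s", 0, str(NODATA)),
    ]
    vals = np.where(np.isnan(grid.values), NODATA, grid.values)
    tifffile.imwrite(path, vals[::-1].astype(np.float64), extratags=extratags)


def _read_geotiff(path: str) -> RasterGrid:
    import tifffile
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        nodata = float(tags[_GDAL_NODATA].value) if _GDAL_NODATA in tags else NODATA
    cell = float(scale[0])
    left, top = float(tie[3]), float(tie[4])
    vals = np.atleast_2d(vals)[::-1].copy()
    nrows = vals.shape[0]
    x0 = left + cell / 2
    y0 = top - cell / 2 - (nrows - 1) * cell
    vals[vals == nodata] = np.nan
    return RasterGrid((x0, y0), cell, vals)


# ---------------------------------------------------------------------------
# crowns
# ---------------------------------------------------------------------------

def read_crowns(path: str) -> CrownSet:
    """Read crown polygons from a GeoJSON FeatureCollection.

    Feature ids are taken from ``id`` or the ``id`` property when present,
    else assigned sequentially.  MultiPolygons are split into their parts.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features", [gj] if gj.get("type") != "FeatureCollection" else [])
    polys = []
    seq = 0
    for feat in feats:
        fid = feat.get("id", feat.get("properties", {}).get("id"))
        geom = shape(feat["geometry"])
        parts = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
        for part in parts:
            if not part.is_valid:
                raise ValueError(f"crown feature {fid if fid is not None else seq}: "
                                 "self-intersecting or otherwise invalid ring")
            pid = fid if fid is not None and len(parts) == 1 else seq
            polys.append((pid, Polygon(part.exterior.coords,
                                       [r.coords for r in part.interiors])))
            seq += 1
    return CrownSet(polys)


def write_crowns(crowns: CrownSet, path: str) -> None:
    feats = [{"type": "Feature", "id": pid,
              "properties": {"id": pid},
              "geometry": mapping(poly)}
             for pid, poly in crowns.polygons]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
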