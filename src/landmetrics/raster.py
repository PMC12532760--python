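"""Yearly co-registered categorical raster series: loading and cropping.

Rasters must already be in a shared equal-area projection on an identical
cell grid; this module validates co-registration, never resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely

from .catalog import ClassCatalog
from .geotiff import GridGeoref, read_stack


@dataclass
class CategoricalRasterSeries:
    """Yearly categorical grids sharing one geometry and class catalog.

    ``data`` has shape (n_years, rows, cols); ``years`` is ascending.
    ``cell_size`` is in km (equal-area projection assumed, tagged not
    verified beyond the metadata).
    """

    years: list[int]
    data: np.ndarray
    georef: GridGeoref
    nodata: int
    catalog: ClassCatalog
    projection: str = "equal-area"

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[0] != len(self.years):
            raise ValueError("data must be (n_years, rows, cols)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        order = np.argsort(self.years)
        self.years = [self.years[i] for i in order]
        self.data = self.data[order]
        known = set(self.catalog.codes) | {self.nodata}
        present = set(np.unique(self.data).tolist())
        unknown = sorted(present - known)
        if unknown:
            raise ValueError(f"unknown class codes in rasters: {unknown}")

    @property
    def cell_size(self) -> float:
        return self.georef.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise KeyError(f"year {year} not in series") from None

    def grid_for(self, year: int) -> np.ndarray:
        return self.data[self.year_index(year)]


def load_series(paths, class_catalog: ClassCatalog, years=None) -> CategoricalRasterSeries:
    """Load one GeoTIFF per year into a validated series.

    ``years`` defaults to integers parsed from the trailing digits of each
    filename.  Geometry mismatches raise an error naming the offending
    file/year; unknown codes raise an error listing them.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("need at least one raster")
    if years is None:
        years = [_year_from_name(p) for p in paths]
    data, georef, nodata = read_stack(paths)
    if nodata is None:
        raise ValueError("rasters carry no NoData tag")
    return CategoricalRasterSeries(
        years=list(years), data=data, georef=georef, nodata=nodata,
        catalog=class_catalog,
    )


def _year_from_name(path) -> int:
    import re

    stem = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    m = re.search(r"(\d{4})$", stem)
    if not m:
        raise ValueError(f"cannot parse year from filename: {path}")
    return int(m.group(1))


def crop_to_polygon(series: CategoricalRasterSeries, region) -> CategoricalRasterSeries:
    """Mask cells whose centers fall outside ``region`` and clip to its
    bounding window; applied identically to every year.

    ``region`` is a shapely geometry or an iterable of geometries (their
    union is used).  Cell centers exactly on the region boundary are kept.
    """
    geom = _as_geometry(region)
    rows, cols = series.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = series.georef.cell_center(rr, cc)
    inside = shapely.intersects_xy(geom, x.ravel(), y.ravel()).reshape(rows, cols)
    if not inside.any():
        raise ValueError("region does not intersect any cell center")
    r_idx = np.nonzero(inside.any(axis=1))[0]
    c_idx = np.nonzero(inside.any(axis=0))[0]
    r0, r1 = int(r_idx[0]), int(r_idx[-1]) + 1
    c0, c1 = int(c_idx[0]), int(c_idx[-1]) + 1
    data = series.data[:, r0:r1, c0:c1].copy()
    data[:, ~inside[r0:r1, c0:c1]] = series.nodata
    return replace(series, data=data, georef=series.georef.shifted(r0, c0))


def _as_geometry(region):
    if isinstance(region, shapely.Geometry):
        return region
    return shapely.union_all([g for g in region])


def read_geojson(path) -> list[tuple[str, shapely.Geometry]]:
    """(label, geometry) pairs from a GeoJSON FeatureCollection.

    The label is the feature's ``name`` or ``continent`` property, else the
    feature index as a string.
    """
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    out = []
    for i, f in enumerate(feats):
        props = f.get("properties") or {}
        label = props.get("name") or props.get("continent") or str(i)
        out.append((label, shapely.geometry.shape(f["geometry"])))
    return out
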