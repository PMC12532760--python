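"""Single-band categorical GeoTIFF read/write.

Thin layer over :mod:`tifffile` handling the three GeoTIFF/GDAL tags the
pipeline needs: ``ModelPixelScaleTag`` (33550), ``ModelTiepointTag`` (33922)
and ``GDAL_NODATA`` (42113).  Only north-up, square-pixel rasters are
supported, which is all a regular-grid tessellation can use anyway.
Coordinates are in the raster's projected units (the pipeline uses km).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113


@dataclass(frozen=True)
class GridGeoref:
    """North-up georeferencing: top-left corner and square cell size."""

    x0: float
    y0: float
    cell_size: float

    def cell_center(self, row, col):
        """Projected coordinates of cell centers (vectorized)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def shifted(self, row0: int, col0: int) -> "GridGeoref":
        return GridGeoref(
            self.x0 + col0 * self.cell_size,
            self.y0 - row0 * self.cell_size,
            self.cell_size,
        )


def write_categorical(path, data: np.ndarray, georef: GridGeoref, nodata: int) -> None:
    """Write a single-band integer raster with georeferencing tags."""
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError("expected a single-band 2D array")
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (georef.cell_size, georef.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, georef.x0, georef.y0, 0.0)),
        (_TAG_NODATA, "s", 0, str(int(nodata))),
    ]
    tifffile.imwrite(path, data, extratags=extratags, photometric="minisblack")


def read_categorical(path) -> tuple[np.ndarray, GridGeoref, int | None]:
    """Read a single-band integer raster; returns (array, georef, nodata)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        nod = tags.get(_TAG_NODATA)
        scale_v = tuple(scale.value) if scale is not None else None
        tie_v = tuple(tie.value) if tie is not None else None
        nod_v = nod.value if nod is not None else None
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    if scale_v is None or tie_v is None:
        raise ValueError(f"{path}: missing georeferencing tags")
    sx, sy = float(scale_v[0]), float(scale_v[1])
    if not np.isclose(sx, sy):
        raise ValueError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    # tiepoint maps raster (i, j, k) -> model (x, y, z); anchored at (0, 0)
    i, j = float(tie_v[0]), float(tie_v[1])
    x, y = float(tie_v[3]), float(tie_v[4])
    x0 = x - j * sx
    y0 = y + i * sy
    nodata = int(float(nod_v)) if nod_v is not None else None
    return data, GridGeoref(x0, y0, sx), nodata


def read_stack(paths) -> tuple[np.ndarray, GridGeoref, int | None]:
    """Read co-registered rasters into one (n, rows, cols) stack.

    Raises if geometry or nodata differ between files; the error names the
    offending file.
    """
    arrays, georef, nodata = [], None, None
    for p in paths:
        a, g, nd = read_categorical(p)
        if georef is None:
            georef, nodata = g, nd
        else:
            same = (
                a.shape == arrays[0].shape
                and np.isclose(g.cell_size, georef.cell_size)
                and np.isclose(g.x0, georef.x0)
                and np.isclose(g.y0, georef.y0)
            )
            if not same:
                raise ValueError(f"raster geometry mismatch in {Path(p).name}")
            if nd != nodata:
                raise ValueError(f"NoData mismatch in {Path(p).name}")
        arrays.append(a)
    return np.stack(arrays), georef, nodata
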