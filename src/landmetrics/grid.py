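"""Regular landscape grids: square tessellations of a raster series.

A landscape grid partitions the raster into square windows ("landscapes")
of one extent.  Windows are anchored at the raster's top-left origin and
trailing partial rows/columns are dropped, so every landscape is full
sized and extents stay comparable.  Windows that are entirely ocean or
NoData in every year are removed, mirroring how terrestrial grids are
built for global analyses; windows with any land (or inland water) in any
year survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .raster import CategoricalRasterSeries

GRID_COLUMNS = ["landscape_id", "extent_km", "lrow", "lcol", "row0", "col0",
                "centroid_x", "centroid_y", "continent"]


@dataclass
class LandscapeGrid:
    """Tessellation of one raster series at one extent.

    ``extent_km`` is the landscape side length in km.  ``entries`` has one
    row per kept landscape: landscape_id (lrow * n_lcols + lcol, stable
    under ocean removal), grid position, top-left cell indices, projected
    centroid, and an optional continent label.
    """

    extent_km: float
    cells_per_side: int
    n_lrows: int
    n_lcols: int
    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        ids = self.entries["landscape_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate landscape ids")
        self._by_id = self.entries.set_index("landscape_id", drop=False)

    def __len__(self):
        return len(self.entries)

    @property
    def landscape_ids(self) -> list[int]:
        return self.entries["landscape_id"].tolist()

    def window(self, landscape_id: int) -> tuple[int, int]:
        try:
            e = self._by_id.loc[landscape_id]
        except KeyError:
            raise KeyError(f"unknown landscape id {landscape_id}") from None
        return int(e["row0"]), int(e["col0"])


def build_grid(series: CategoricalRasterSeries, extent_km: float) -> LandscapeGrid:
    """Build the landscape grid at one extent (side length in km).

    ``extent_km`` must be an integer multiple of the cell size.  Raises if
    no landscape survives the all-ocean/NoData removal rule.
    """
    cps = extent_km / series.cell_size
    if abs(cps - round(cps)) > 1e-9:
        raise ValueError(
            f"extent {extent_km} km is not a multiple of the {series.cell_size} km cell size"
        )
    cps = int(round(cps))
    rows, cols = series.shape
    n_lrows, n_lcols = rows // cps, cols // cps
    if n_lrows == 0 or n_lcols == 0:
        raise ValueError("raster smaller than one landscape window")

    # a window is removable iff every cell is ocean or NoData in every year
    drop_codes = set(series.catalog.ocean_codes) | {series.nodata}
    all_drop = np.isin(series.data, sorted(drop_codes)).all(axis=0)

    recs = []
    for lr in range(n_lrows):
        for lc in range(n_lcols):
            r0, c0 = lr * cps, lc * cps
            if all_drop[r0 : r0 + cps, c0 : c0 + cps].all():
                continue
            cx = series.georef.x0 + (c0 + cps / 2) * series.cell_size
            cy = series.georef.y0 - (r0 + cps / 2) * series.cell_size
            recs.append(
                (lr * n_lcols + lc, extent_km, lr, lc, r0, c0, cx, cy, "unassigned")
            )
    if not recs:
        raise ValueError("no landscape windows survive ocean/NoData removal")
    entries = pd.DataFrame(recs, columns=GRID_COLUMNS)
    return LandscapeGrid(extent_km, cps, n_lrows, n_lcols, entries)


def extract_landscape(series: CategoricalRasterSeries, grid: LandscapeGrid,
                      landscape_id: int, year: int) -> np.ndarray:
    """Read-only square window for one landscape and year."""
    r0, c0 = grid.window(landscape_id)
    cps = grid.cells_per_side
    view = series.grid_for(year)[r0 : r0 + cps, c0 : c0 + cps]
    view.flags.writeable = False if view.base is not None else view.flags.writeable
    return view


def assign_continents(grid: LandscapeGrid, continents) -> LandscapeGrid:
    """Label each landscape by the first polygon covering its centroid.

    ``continents`` is an ordered iterable of (label, shapely geometry).
    Centroids on a shared boundary get the first matching label; centroids
    in no polygon stay "unassigned".
    """
    continents = list(continents)
    labels = []
    for _, e in grid.entries.iterrows():
        pt_x, pt_y = e["centroid_x"], e["centroid_y"]
        label = "unassigned"
        for name, geom in continents:
            if shapely.intersects_xy(geom, pt_x, pt_y):
                label = name
                break
        labels.append(label)
    entries = grid.entries.copy()
    entries["continent"] = labels
    return LandscapeGrid(grid.extent_km, grid.cells_per_side, grid.n_lrows,
                         grid.n_lcols, entries)


def grid_to_csv(grid: LandscapeGrid, path) -> None:
    grid.entries.to_csv(path, index=False)
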