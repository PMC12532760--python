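"""Class-level landscape metrics on categorical raster windows.

Implements the six metrics used throughout the pipeline:

========  =============================================  =============
metric    definition                                     units
========  =============================================  =============
CA        total area of a class in the landscape         km^2
NP        number of patches (connected components)       count
TE        total edge length between the class and any    km
          other class (window boundary optional)
TCA       total core area: cells all of whose            km^2
          neighbours are the same class
NDCA      number of disjunct core-area patches           count
LSI       landscape shape index: class edge length /     dimensionless
          minimum possible edge length of an equally
          sized maximally aggregated (square-like) class
========  =============================================  =============

Conventions (all exposed in :class:`MetricsConfig`):

* patch connectivity defaults to 8 (queen), core neighbourhood to 4 (rook);
* TE excludes the window's outer boundary by default, while the LSI edge
  term always includes it — this pairing reproduces the standard
  FRAGSTATS-lineage definitions the metrics descend from;
* cells at the window border are never core (a missing neighbour counts as
  a different class), as do water and NoData neighbours;
* edge lengths are accumulated as exact integer face counts and scaled by
  the cell size only at the end, so TE and the LSI numerator carry no
  floating-point accumulation error.

When a class is absent from a landscape, CA, NP, TE, TCA and NDCA are zero
by definition; LSI is undefined (0/0) and is reported as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .catalog import ClassCatalog

#: connectivity structuring elements for scipy.ndimage.label
_STRUCT = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}

ZERO_WHEN_ABSENT = ("CA", "NP", "TE", "TCA", "NDCA")
MISSING_WHEN_ABSENT = ("LSI",)
METRIC_NAMES = ZERO_WHEN_ABSENT + MISSING_WHEN_ABSENT


@dataclass(frozen=True)
class MetricsConfig:
    """Conventions fixed for one metrics run."""

    cell_size: float = 1.0  # km per cell side
    connectivity: int = 8  # patch connectivity (4 or 8)
    core_neighborhood: int = 4  # neighbourhood for core-cell test (4 or 8)
    count_boundary: bool = False  # include window boundary faces in TE

    def __post_init__(self):
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.core_neighborhood not in (4, 8):
            raise ValueError("core_neighborhood must be 4 or 8")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


@dataclass
class MetricRecord:
    """One metric value for one (landscape, year, class)."""

    landscape_id: int
    year: int
    class_code: int
    metric: str
    value: float
    missing: bool = False


def label_patches(window: np.ndarray, class_code: int, connectivity: int = 8):
    """Label maximal connected components of ``class_code`` cells.

    Returns ``(labels, count)`` where ``labels`` is an int array with 0 for
    non-class cells and 1..count for patches.
    """
    if connectivity not in _STRUCT:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(window) == class_code
    labels, count = ndimage.label(mask, structure=_STRUCT[connectivity])
    return labels, int(count)


def class_area(window: np.ndarray, class_code: int, cell_size: float = 1.0) -> float:
    """Total class area in km^2: cell count times cell area."""
    n = int(np.count_nonzero(np.asarray(window) == class_code))
    return n * cell_size * cell_size


def _edge_faces(mask: np.ndarray, count_boundary: bool) -> int:
    """Count cell faces separating ``mask`` cells from non-mask cells.

    Interior faces are 4-adjacent pairs with exactly one cell in the mask;
    boundary faces (against the window edge) are added when requested.
    """
    m = mask.astype(np.int8)
    faces = int(np.abs(np.diff(m, axis=0)).sum()) + int(np.abs(np.diff(m, axis=1)).sum())
    if count_boundary:
        faces += int(m[0, :].sum() + m[-1, :].sum() + m[:, 0].sum() + m[:, -1].sum())
    return faces


def total_edge(
    window: np.ndarray,
    class_code: int,
    cell_size: float = 1.0,
    count_boundary: bool = False,
) -> float:
    """Total edge length in km; water and NoData neighbours count as edge."""
    mask = np.asarray(window) == class_code
    return _edge_faces(mask, count_boundary) * cell_size


def min_edge_faces(n: int) -> int:
    """Minimum perimeter, in faces, of any polyomino of ``n`` cells.

    The most aggregated arrangement of n cells is a square-like spiral:
    with m = floor(sqrt(n)), the minimum perimeter is 4m when n = m^2,
    4m + 2 when n <= m(m+1), and 4m + 4 otherwise.
    """
    if n < 0:
        raise ValueError("cell count must be non-negative")
    if n == 0:
        return 0
    m = math.isqrt(n)
    if m * m == n:
        return 4 * m
    if n <= m * (m + 1):
        return 4 * m + 2
    return 4 * m + 4


def lsi(window: np.ndarray, class_code: int) -> float | None:
    """Landscape shape index; ``None`` when the class is absent.

    The edge term includes the window boundary, so a landscape entirely
    covered by one class has LSI exactly 1 (its edge equals the minimum
    possible for that many cells).  Both terms are integers in face units,
    so the ratio is exact up to one float division.
    """
    mask = np.asarray(window) == class_code
    n = int(mask.sum())
    if n == 0:
        return None
    return _edge_faces(mask, count_boundary=True) / min_edge_faces(n)


def core_mask(window: np.ndarray, class_code: int, core_neighborhood: int = 4) -> np.ndarray:
    """Boolean mask of core cells: class cells whose every neighbour in the
    chosen neighbourhood exists and carries the same class.

    Window-border cells are never core; water and NoData neighbours
    disqualify a cell exactly like any other different class.
    """
    if core_neighborhood not in (4, 8):
        raise ValueError("core_neighborhood must be 4 or 8")
    mask = np.asarray(window) == class_code
    if mask.size == 0:
        return mask
    core = mask.copy()
    # missing neighbours at the border disqualify
    core[0, :] = core[-1, :] = False
    core[:, 0] = core[:, -1] = False
    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if core_neighborhood == 8:
        shifts += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    inner = core[1:-1, 1:-1]
    r, c = mask.shape
    for dr, dc in shifts:
        inner &= mask[1 + dr : r - 1 + dr, 1 + dc : c - 1 + dc]
    return core


def total_core_area(window: np.ndarray, class_code: int, cell_size: float = 1.0,
                    core_neighborhood: int = 4) -> float:
    """Total core area (TCA) in km^2."""
    n = int(core_mask(window, class_code, core_neighborhood).sum())
    return n * cell_size * cell_size


def ndca(window: np.ndarray, class_code: int, connectivity: int = 8,
         core_neighborhood: int = 4) -> int:
    """Number of disjunct core-area patches ('patches within patches')."""
    core = core_mask(window, class_code, core_neighborhood)
    _, count = ndimage.label(core, structure=_STRUCT[connectivity])
    return int(count)


def compute_class_metrics(window: np.ndarray, class_code: int,
                          config: MetricsConfig) -> dict[str, float | None]:
    """All six metrics for one class in one window; LSI is ``None`` when
    the class is absent."""
    window = np.asarray(window)
    mask = window == class_code
    n = int(mask.sum())
    cs = config.cell_size
    _, n_patches = ndimage.label(mask, structure=_STRUCT[config.connectivity])
    core = core_mask(window, class_code, config.core_neighborhood)
    _, n_core = ndimage.label(core, structure=_STRUCT[config.connectivity])
    return {
        "CA": n * cs * cs,
        "NP": float(n_patches),
        "TE": _edge_faces(mask, config.count_boundary) * cs,
        "TCA": int(core.sum()) * cs * cs,
        "NDCA": float(n_core),
        "LSI": (_edge_faces(mask, True) / min_edge_faces(n)) if n else None,
    }


def compute_landscape_metrics(
    window: np.ndarray,
    classes,
    config: MetricsConfig,
    landscape_id: int = 0,
    year: int = 0,
) -> list[MetricRecord]:
    """Metric records for every land class in one landscape window.

    ``classes`` may be a :class:`ClassCatalog` or an iterable of land class
    codes.  Water-class records are never emitted; a window with no land
    cells at all yields no records.  Absent classes get value 0 for the
    zero-semantics metrics and a missing LSI.
    """
    window = np.asarray(window)
    if isinstance(classes, ClassCatalog):
        land_codes = classes.land_codes
    else:
        land_codes = list(classes)
    if not np.isin(window, land_codes).any():
        return []
    records: list[MetricRecord] = []
    for code in land_codes:
        vals = compute_class_metrics(window, code, config)
        for name in METRIC_NAMES:
            v = vals[name]
            records.append(
                MetricRecord(landscape_id, year, code, name,
                             float("nan") if v is None else float(v),
                             missing=v is None)
            )
    return records


def apply_absence_rules(records, catalog_zero=ZERO_WHEN_ABSENT,
                        catalog_missing=MISSING_WHEN_ABSENT):
    """Replace missing values with 0 for metrics where absence means zero.

    Accepts a list of :class:`MetricRecord` or a long-format DataFrame with
    ``metric``/``value``/``missing`` columns; returns the same kind.
    Metrics with missing-semantics (LSI) are left untouched.
    """
    known = set(catalog_zero) | set(catalog_missing)

    if isinstance(records, pd.DataFrame):
        unknown = set(records["metric"].unique()) - known
        if unknown:
            raise ValueError(f"unknown metric names: {sorted(unknown)}")
        out = records.copy()
        fix = out["missing"] & out["metric"].isin(catalog_zero)
        out.loc[fix, "value"] = 0.0
        out.loc[fix, "missing"] = False
        return out

    out = []
    for rec in records:
        if rec.metric not in known:
            raise ValueError(f"unknown metric name: {rec.metric}")
        if rec.missing and rec.metric in catalog_zero:
            rec = replace(rec, value=0.0, missing=False)
        out.append(rec)
    return out


def records_to_frame(records, extent_km: float | None = None) -> pd.DataFrame:
    """Long-format DataFrame (landscape_id, [extent_km,] year, class,
    metric, value, missing) from metric records."""
    df = pd.DataFrame(
        {
            "landscape_id": [r.landscape_id for r in records],
            "year": [r.year for r in records],
            "class": [r.class_code for r in records],
            "metric": [r.metric for r in records],
            "value": [r.value for r in records],
            "missing": [r.missing for r in records],
        }
    )
    if extent_km is not None:
        df.insert(1, "extent_km", extent_km)
    return df
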