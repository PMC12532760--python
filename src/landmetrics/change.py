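"""Landscape-pattern change analysis.

Quantifies how landscape composition and configuration change over time:

* yearly mean/SD trends of every metric across landscapes (globally or per
  continent);
* per-landscape net change of every metric between two years;
* the nine-category directional classification crossing change in class
  area (CA: composition) with change in the landscape shape index (LSI:
  fragmentation per se, i.e. configuration independent of area) — each of
  ΔCA and ΔLSI mapped to +/−/=, applied only to landscapes containing the
  class in both years;
* category frequency tables and continental net-change summaries.

"No change" is exact for CA (cell counts are integers, so equal areas
subtract to exactly zero) and uses a tiny relative tolerance for LSI,
whose single float division can differ in the last bit between equal
configurations.  Sample (n-1) standard deviations throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grid import LandscapeGrid
from .metrics import MISSING_WHEN_ABSENT

CATEGORY_LABELS = [
    "CA+LSI+", "CA+LSI-", "CA+LSI=",
    "CA-LSI+", "CA-LSI-", "CA-LSI=",
    "CA=LSI+", "CA=LSI-", "CA=LSI=",
]
#: raster codes for category maps: 1..9 for the labels above
CATEGORY_CODES = {label: i + 1 for i, label in enumerate(CATEGORY_LABELS)}
ABSENT_CODE = 0  # class not present in both years (excluded from classification)
NO_LANDSCAPE_CODE = 255  # window not part of the grid (ocean-removed / dropped)

LSI_REL_TOL = 1e-9


def annual_summary(records: pd.DataFrame, by_continent: bool = False,
                   grid: LandscapeGrid | None = None) -> pd.DataFrame:
    """Mean and sample SD per (extent, class, metric, year[, continent]).

    Records must have absence rules applied; missing-semantics metrics
    (LSI) contribute only their defined values.  Groups with no defined
    records are omitted with a warning.
    """
    df = records
    if by_continent:
        if grid is None:
            raise ValueError("continent summaries need the landscape grid")
        cont = grid.entries.set_index("landscape_id")["continent"]
        df = df.assign(continent=df["landscape_id"].map(cont))
    defined = df[~df["missing"]]
    n_dropped = (
        df[df["missing"]].groupby(["extent_km", "class", "metric", "year"])
        .size()
    )
    keys = ["extent_km", "class", "metric", "year"]
    if by_continent:
        keys.append("continent")
    grouped = defined.groupby(keys)["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    all_groups = df.groupby(keys).size()
    empty = set(all_groups.index) - set(
        defined.groupby(keys).size().index
    )
    for g in sorted(empty, key=str):
        warnings.warn(f"group {g} has no defined values; omitted")
    return out


def net_change(records: pd.DataFrame, year0: int, year1: int) -> pd.DataFrame:
    """Per-landscape net change of every metric between two years.

    Returns one row per (landscape, extent, class, metric) with ``delta``
    and a ``present_both`` flag (CA > 0 in both years for that class).  A
    Δ is emitted only when the metric is defined in both years, so LSI
    rows exist only where the class is present at both endpoints.
    """
    for y in (year0, year1):
        if y not in set(records["year"]):
            raise ValueError(f"year {y} not in records")
    idx = ["landscape_id", "extent_km", "class", "metric"]
    r0 = records[records["year"] == year0].set_index(idx)
    r1 = records[records["year"] == year1].set_index(idx)
    joined = r0[["value", "missing"]].join(
        r1[["value", "missing"]], how="inner", lsuffix="_0", rsuffix="_1"
    )
    ok = ~(joined["missing_0"] | joined["missing_1"])
    joined = joined[ok]
    out = joined.reset_index()
    out["delta"] = out["value_1"] - out["value_0"]

    ca = out[out["metric"] == "CA"].set_index(["landscape_id", "extent_km", "class"])
    present = (ca["value_0"] > 0) & (ca["value_1"] > 0)
    out["present_both"] = (
        out.set_index(["landscape_id", "extent_km", "class"]).index.map(present)
    )
    out["present_both"] = out["present_both"].fillna(False).astype(bool)
    return out[idx + ["value_0", "value_1", "delta", "present_both"]]


def _sign(delta: float, tol: float) -> str:
    if abs(delta) <= tol:
        return "="
    return "+" if delta > 0 else "-"


def classify_ca_lsi(delta_ca: float, delta_lsi: float,
                    lsi0: float | None = None, lsi1: float | None = None,
                    ca_tol: float = 0.0,
                    lsi_rel_tol: float = LSI_REL_TOL) -> str:
    """Map (ΔCA, ΔLSI) to one of the nine directional categories.

    ΔCA is compared exactly by default (areas are integer cell counts times
    a constant); ΔLSI uses a relative tolerance against the endpoint
    magnitudes.  Callers must ensure the class is present in both years —
    classification of a non-present landscape is the caller's exclusion,
    not a tenth category.
    """
    ca_sign = _sign(delta_ca, ca_tol)
    scale = max(abs(lsi0 or 0.0), abs(lsi1 or 0.0), 1.0)
    lsi_sign = _sign(delta_lsi, lsi_rel_tol * scale)
    return f"CA{ca_sign}LSI{lsi_sign}"


def classify_landscapes(net: pd.DataFrame, class_code: int,
                        extent_km: float | None = None) -> pd.DataFrame:
    """Nine-category classification for one class over all landscapes where
    the class is present in both years.

    Returns (landscape_id, extent_km, class, category); landscapes without
    the class at both endpoints are excluded, not categorised.
    """
    sub = net[net["class"] == class_code]
    if extent_km is not None:
        sub = sub[sub["extent_km"] == extent_km]
    ca = sub[(sub["metric"] == "CA") & sub["present_both"]]
    lsi = sub[sub["metric"] == "LSI"].set_index(["landscape_id", "extent_km"])
    rows = []
    for _, e in ca.iterrows():
        key = (e["landscape_id"], e["extent_km"])
        if key not in lsi.index:
            continue  # LSI undefined at an endpoint despite CA > 0 cannot occur
        le = lsi.loc[key]
        cat = classify_ca_lsi(e["delta"], le["delta"],
                              lsi0=le["value_0"], lsi1=le["value_1"])
        rows.append((e["landscape_id"], e["extent_km"], class_code, cat))
    return pd.DataFrame(rows, columns=["landscape_id", "extent_km", "class",
                                       "category"])


def category_frequencies(categories: pd.DataFrame,
                         grid: LandscapeGrid | None = None,
                         by_continent: bool = False) -> pd.DataFrame:
    """Percentage of classified landscapes in each of the nine categories.

    One row per (class, extent[, continent], category); percentages sum to
    100 within each scope.  Raises on an empty scope.
    """
    if categories.empty:
        raise ValueError("no classified landscapes in scope")
    df = categories
    keys = ["class", "extent_km"]
    if by_continent:
        if grid is None:
            raise ValueError("continental frequencies need the landscape grid")
        cont = grid.entries.set_index("landscape_id")["continent"]
        df = df.assign(continent=df["landscape_id"].map(cont))
        keys.append("continent")
    rows = []
    for scope, g in df.groupby(keys):
        n = len(g)
        counts = g["category"].value_counts()
        for label in CATEGORY_LABELS:
            pct = 100.0 * counts.get(label, 0) / n
            rows.append((*scope, label, pct, n))
    return pd.DataFrame(rows, columns=keys + ["category", "percent", "n"])


def continental_net_change(net: pd.DataFrame, grid: LandscapeGrid) -> pd.DataFrame:
    """Mean and sample SD of Δ per continent x class x metric (one extent's
    grid).  Unassigned landscapes report under the label "unassigned"."""
    cont = grid.entries.set_index("landscape_id")["continent"]
    df = net.assign(continent=net["landscape_id"].map(cont))
    out = (
        df.groupby(["continent", "class", "metric"])["delta"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size")
        .reset_index()
    )
    return out


def category_map(categories: pd.DataFrame, grid: LandscapeGrid,
                 class_code: int) -> np.ndarray:
    """Integer raster of the nine categories at landscape resolution.

    Codes: 1..9 per :data:`CATEGORY_CODES`, 0 for landscapes where the
    class is absent at an endpoint (excluded), 255 for windows not in the
    grid.
    """
    arr = np.full((grid.n_lrows, grid.n_lcols), NO_LANDSCAPE_CODE, np.uint8)
    pos = grid.entries.set_index("landscape_id")[["lrow", "lcol"]]
    arr[pos["lrow"].to_numpy(), pos["lcol"].to_numpy()] = ABSENT_CODE
    sub = categories[categories["class"] == class_code]
    for _, e in sub.iterrows():
        lr, lc = pos.loc[e["landscape_id"]]
        arr[int(lr), int(lc)] = CATEGORY_CODES[e["category"]]
    return arr
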