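"""End-to-end orchestration: simulate/load -> grid -> metrics -> scaling ->
change analysis -> reports, with a run manifest.

Outputs are plain CSV files with stable, documented columns, written in a
deterministic sort order so identical configuration and seed give
byte-identical files regardless of worker count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .catalog import ClassCatalog
from .change import (annual_summary, category_frequencies, category_map,
                     classify_landscapes, continental_net_change, net_change,
                     CATEGORY_CODES, ABSENT_CODE, NO_LANDSCAPE_CODE)
from .geotiff import GridGeoref, write_categorical
from .grid import LandscapeGrid, assign_continents, build_grid, extract_landscape, grid_to_csv
from .metrics import (METRIC_NAMES, MetricsConfig, apply_absence_rules,
                      compute_landscape_metrics, records_to_frame)
from .raster import CategoricalRasterSeries, crop_to_polygon, load_series, read_geojson
from .scaling import scaling_report
from .synthetic import SyntheticScenario, generate_series


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    extents_km: list[float]
    change_years: tuple[int, int]
    scenario: SyntheticScenario | None = None
    raster_paths: list[str] | None = None
    catalog: ClassCatalog | None = None  # required with raster_paths
    region_geojson: str | None = None
    continents_geojson: str | None = None
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    r2_threshold: float = 0.98
    seed: int = 0
    workers: int = 1
    out_dir: str = "out"

    def validate_against(self, series: CategoricalRasterSeries) -> None:
        for ext in self.extents_km:
            cps = ext / series.cell_size
            if ext <= 0 or abs(cps - round(cps)) > 1e-9:
                raise ValueError(
                    f"extent {ext} km is not a positive multiple of the "
                    f"{series.cell_size} km cell size"
                )
        y0, y1 = self.change_years
        if not (y0 < y1):
            raise ValueError("change_years must satisfy year0 < year1")
        for y in (y0, y1):
            if y not in series.years:
                raise ValueError(f"change year {y} not in series years")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        scenario = None
        if doc.get("scenario"):
            scen_path = Path(path).parent / doc["scenario"]
            scenario = SyntheticScenario.from_yaml(scen_path)
            if "seed" in doc:
                scenario.seed = int(doc["seed"])
        mc = doc.get("metrics", {})
        return cls(
            extents_km=[float(e) for e in doc["extents_km"]],
            change_years=tuple(doc["change_years"]),
            scenario=scenario,
            raster_paths=doc.get("rasters"),
            region_geojson=doc.get("region"),
            continents_geojson=doc.get("continents"),
            metrics=MetricsConfig(
                cell_size=float(mc.get("cell_size_km", scenario.cell_size if scenario else 1.0)),
                connectivity=int(mc.get("connectivity", 8)),
                core_neighborhood=int(mc.get("core_neighborhood", 4)),
                count_boundary=bool(mc.get("count_boundary", False)),
            ),
            r2_threshold=float(doc.get("r2_threshold", 0.98)),
            seed=int(doc.get("seed", 0)),
            workers=int(doc.get("workers", 1)),
            out_dir=doc.get("out_dir", "out"),
        )


SORT_KEYS = ["extent_km", "landscape_id", "year", "class", "metric"]


def compute_all_metrics(series: CategoricalRasterSeries, grid: LandscapeGrid,
                        config: MetricsConfig, years=None,
                        workers: int = 1) -> pd.DataFrame:
    """Metric records for every landscape x year x land class at one extent.

    Embarrassingly parallel over landscapes; output order is fixed by a
    final sort, so the worker count never affects content or ordering.
    """
    years = list(series.years) if years is None else list(years)
    land = series.catalog.land_codes

    def one_landscape(lid: int):
        recs = []
        for year in years:
            window = extract_landscape(series, grid, lid, year)
            recs.extend(
                compute_landscape_metrics(window, land, config,
                                          landscape_id=lid, year=year)
            )
        return recs

    ids = grid.landscape_ids
    if workers == 1:
        chunks = [one_landscape(lid) for lid in ids]
    else:
        chunks = Parallel(n_jobs=workers)(delayed(one_landscape)(lid) for lid in ids)
    records = [r for chunk in chunks for r in chunk]
    df = records_to_frame(records, extent_km=grid.extent_km)
    df = apply_absence_rules(df)
    return df.sort_values(SORT_KEYS, kind="stable").reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write outputs; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": {}}

    # -- input series -------------------------------------------------------
    if config.scenario is not None:
        scenario = config.scenario
        scenario.seed = config.seed
        series, truth_log = generate_series(scenario)
        truth_log.to_csv(out / "truth_log.csv", index=False)
        manifest["stages"]["simulate"] = {"rows": len(truth_log)}
    elif config.raster_paths:
        if config.catalog is None:
            raise ValueError("raster input needs a class catalog")
        series = load_series(config.raster_paths, config.catalog)
        manifest["stages"]["load"] = {"years": len(series.years)}
    else:
        raise ValueError("config needs a scenario or raster paths")

    if config.region_geojson:
        region = [g for _, g in read_geojson(config.region_geojson)]
        series = crop_to_polygon(series, region)
    config.validate_against(series)
    mconfig = MetricsConfig(
        cell_size=series.cell_size,
        connectivity=config.metrics.connectivity,
        core_neighborhood=config.metrics.core_neighborhood,
        count_boundary=config.metrics.count_boundary,
    )

    continents = (read_geojson(config.continents_geojson)
                  if config.continents_geojson else None)

    # -- grids and metrics --------------------------------------------------
    all_records = []
    grids: dict[float, LandscapeGrid] = {}
    for ext in config.extents_km:
        g = build_grid(series, ext)
        if continents:
            g = assign_continents(g, continents)
        grids[ext] = g
        grid_to_csv(g, out / f"grid_{_fmt_ext(ext)}km.csv")
        df = compute_all_metrics(series, g, mconfig, workers=config.workers)
        all_records.append(df)
    records = pd.concat(all_records, ignore_index=True)
    records = records.sort_values(SORT_KEYS, kind="stable").reset_index(drop=True)
    records.to_csv(out / "metrics.csv", index=False)
    manifest["stages"]["metrics"] = {"rows": len(records)}

    # -- scaling ------------------------------------------------------------
    fits, verdicts = scaling_report(records, METRIC_NAMES,
                                    series.catalog.land_codes,
                                    config.r2_threshold)
    fits.to_csv(out / "scaling_fits.csv", index=False)
    verdicts.to_csv(out / "scaling_verdicts.csv", index=False)
    manifest["stages"]["scaling"] = {"fits": len(fits)}

    # -- change analysis ----------------------------------------------------
    trends = annual_summary(records)
    trends = trends.sort_values(["extent_km", "class", "metric", "year"],
                                kind="stable").reset_index(drop=True)
    trends.to_csv(out / "trends.csv", index=False)

    y0, y1 = config.change_years
    net = net_change(records, y0, y1)
    net = net.sort_values(["extent_km", "landscape_id", "class", "metric"],
                          kind="stable").reset_index(drop=True)
    net.to_csv(out / "net_change.csv", index=False)

    cats = []
    for ext in config.extents_km:
        for code in series.catalog.land_codes:
            c = classify_landscapes(net, code, extent_km=ext)
            if not c.empty:
                cats.append(c)
    categories = (pd.concat(cats, ignore_index=True) if cats
                  else pd.DataFrame(columns=["landscape_id", "extent_km",
                                             "class", "category"]))
    categories = categories.sort_values(["extent_km", "class", "landscape_id"],
                                        kind="stable").reset_index(drop=True)
    categories.to_csv(out / "categories.csv", index=False)
    if not categories.empty:
        freqs = category_frequencies(categories)
        freqs.to_csv(out / "category_frequencies.csv", index=False)
        manifest["stages"]["change"] = {"net_rows": len(net),
                                        "classified": len(categories)}
        smallest = min(config.extents_km)
        g = grids[smallest]
        code_table = [{"code": NO_LANDSCAPE_CODE, "meaning": "no landscape"},
                      {"code": ABSENT_CODE, "meaning": "class absent in a change year"}]
        code_table += [{"code": v, "meaning": k} for k, v in CATEGORY_CODES.items()]
        (out / "category_codes.json").write_text(json.dumps(code_table, indent=1))
        lgeoref = GridGeoref(series.georef.x0, series.georef.y0,
                             series.cell_size * g.cells_per_side)
        for code in series.catalog.land_codes:
            arr = category_map(categories[categories["extent_km"] == smallest],
                               g, code)
            write_categorical(out / f"category_map_class{code}_{_fmt_ext(smallest)}km.tif",
                              arr, lgeoref, NO_LANDSCAPE_CODE)
        if continents:
            cont_net = continental_net_change(
                net[net["extent_km"] == smallest], g)
            cont_net.to_csv(out / "continental_net_change.csv", index=False)
            cfreq = category_frequencies(
                categories[categories["extent_km"] == smallest], g,
                by_continent=True)
            cfreq.to_csv(out / "continental_category_frequencies.csv", index=False)

    manifest["config_hash"] = _config_hash(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _fmt_ext(ext: float) -> str:
    return f"{ext:g}"


def _config_hash(config: RunConfig) -> str:
    doc = {
        "extents": config.extents_km,
        "change_years": list(config.change_years),
        "seed": config.seed,
        "r2_threshold": config.r2_threshold,
        "metrics": [config.metrics.connectivity, config.metrics.core_neighborhood,
                    config.metrics.count_boundary],
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]
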