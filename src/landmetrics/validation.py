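"""Desk-scale validation studies run against the synthetic generator.

Two designed experiments with known ground truth:

* :func:`stationary_scaling_study` — on stationary-composition maps the
  expected class area in a landscape of side L is p * L^2, so the mean-CA
  scaling fit must recover a power law with exponent 2; LSI, whose edge
  term grows with L and whose minimum-edge term grows like L for a fixed
  composition, is expected to scale linearly.
* :func:`expansion_recovery_study` — one class expands at a known rate
  inside a designated subset of landscapes and is static elsewhere; the
  nine-category CA/LSI classification must recover which landscapes
  changed.

Both are the package's own end-to-end checks; tests assert on their
outputs and the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .change import category_frequencies, classify_landscapes, net_change
from .geotiff import GridGeoref
from .grid import build_grid
from .metrics import MetricsConfig
from .pipeline import compute_all_metrics
from .raster import CategoricalRasterSeries
from .scaling import best_fit, fit_scaling, mean_metric_by_extent
from .synthetic import ChangeOperator, SyntheticScenario, generate_series


def _one_year_series(grid: np.ndarray, scenario: SyntheticScenario) -> CategoricalRasterSeries:
    return CategoricalRasterSeries(
        years=[scenario.years[0]], data=grid[None],
        georef=GridGeoref(0.0, scenario.grid_rows * scenario.cell_size,
                          scenario.cell_size),
        nodata=scenario.nodata, catalog=scenario.catalog(),
    )


def stationary_scaling_study(seed: int = 0, n_seeds: int = 10, size: int = 400,
                             p: float = 0.3,
                             extents=(10.0, 20.0, 40.0)) -> dict:
    """Fit mean-CA and mean-LSI scaling on stationary two-class maps.

    Generates ``n_seeds`` maps of ``size`` x ``size`` cells with class
    frequency ``p``, computes the six metrics on landscape grids at the
    given extents, and fits linear and power-law models to the mean of CA
    and LSI versus landscape side length, pooling landscapes over seeds.
    """
    from .synthetic import generate_initial_map

    frames = []
    for k in range(n_seeds):
        scen = SyntheticScenario(
            grid_rows=size, grid_cols=size, classes=[(1, p), (2, 1 - p)],
            years=(1992, 1992), cluster_density=0.4,
            seed=(seed * 1_000_003 + k) % (2**31 - 1))
        g = generate_initial_map(scen)
        series = _one_year_series(g, scen)
        for ext in extents:
            grid = build_grid(series, float(ext))
            frames.append(compute_all_metrics(series, grid, MetricsConfig()))
    records = pd.concat(frames, ignore_index=True)

    ca_lin, ca_pow = fit_scaling(mean_metric_by_extent(records, "CA", 1), "CA", 1)
    lsi_lin, lsi_pow = fit_scaling(mean_metric_by_extent(records, "LSI", 1), "LSI", 1)
    return {
        "ca_power_exponent": ca_pow.slope,
        "ca_power_r2": ca_pow.r2,
        "lsi_linear_r2": lsi_lin.r2,
        "lsi_power_r2": lsi_pow.r2 if lsi_pow else float("nan"),
        "lsi_best_model": best_fit(lsi_lin, lsi_pow).model,
        "n_landscapes": int(records["landscape_id"].nunique() * n_seeds),
    }


def expansion_recovery_study(seed: int = 0, n_seeds: int = 10,
                             landscape_cells: int = 20,
                             n_lrows: int = 10, n_lcols: int = 10,
                             designated_fraction: float = 0.25,
                             rate: int = 5,
                             years: tuple[int, int] = (1992, 2020)) -> dict:
    """Classify landscapes after confined expansion of one class.

    Every landscape starts with a 3x3 patch of class 1 on a class-2
    background; a designated fraction of landscapes gets an expand
    operator (class 1, ``rate`` cells/year, confined to that landscape's
    window).  Returns the percentage of designated landscapes recovered as
    CA+ and of untouched landscapes recovered as CA=, pooled over seeds,
    plus the nine-category percentage total as a consistency check.
    """
    cps = landscape_cells
    rows, cols = n_lrows * cps, n_lcols * cps
    n_landscapes = n_lrows * n_lcols
    n_designated = round(designated_fraction * n_landscapes)

    designated_hits = untouched_hits = 0
    designated_total = untouched_total = 0
    pct_sums = []
    for k in range(n_seeds):
        sub_seed = (seed * 1_000_003 + k) % (2**31 - 1)
        rng = np.random.default_rng(sub_seed)
        designated = set(rng.choice(n_landscapes, n_designated,
                                    replace=False).tolist())

        initial = np.full((rows, cols), 2, np.uint8)
        operators = []
        for lid in range(n_landscapes):
            r0 = (lid // n_lcols) * cps
            c0 = (lid % n_lcols) * cps
            rc, cc = r0 + cps // 2 - 1, c0 + cps // 2 - 1
            initial[rc - 1 : rc + 2, cc - 1 : cc + 2] = 1
            if lid in designated:
                operators.append(ChangeOperator(
                    years[0] + 1, years[1], "expand", source=1, rate=rate,
                    region=(r0, c0, r0 + cps, c0 + cps)))

        scen = SyntheticScenario(
            grid_rows=rows, grid_cols=cols, classes=[(1, 0.1), (2, 0.9)],
            years=years, cluster_density=0.4, seed=sub_seed,
            operators=operators)
        series, _ = generate_series(scen, initial_map=initial)

        grid = build_grid(series, float(cps))
        records = compute_all_metrics(series, grid, MetricsConfig(),
                                      years=[years[0], years[1]])
        net = net_change(records, years[0], years[1])
        cats = classify_landscapes(net, 1, extent_km=float(cps))
        by_id = cats.set_index("landscape_id")["category"]
        for lid in range(n_landscapes):
            cat = by_id.get(lid)
            if lid in designated:
                designated_total += 1
                if cat is not None and cat.startswith("CA+"):
                    designated_hits += 1
            else:
                untouched_total += 1
                if cat is not None and cat.startswith("CA="):
                    untouched_hits += 1
        pct_sums.append(category_frequencies(cats)["percent"].sum())

    return {
        "designated_ca_plus_pct": 100.0 * designated_hits / designated_total,
        "untouched_ca_eq_pct": 100.0 * untouched_hits / untouched_total,
        "category_pct_sum": float(np.mean(pct_sums)),
        "n_landscapes_per_seed": n_landscapes,
        "n_seeds": n_seeds,
    }
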