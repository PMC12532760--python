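"""Scaling behaviour of landscape metrics across landscape extents.

Screens metrics for predictable (scale-invariant) behaviour: the mean of a
metric over all landscapes of one extent is regressed on landscape side
length, once linearly and once as a power law (ordinary least squares on
log-log axes), and a metric is called scale-predictable when every class
fits one of the two forms tightly *and* the fitted direction agrees across
classes.  Screenings of this kind are traditionally done by visual
inspection of the mean-versus-extent curves; the R-squared threshold
(default 0.98) plus the cross-class direction rule is a reproducible
operationalisation of "smooth linear or power-law relationship", and the
threshold is exposed in configuration so its influence can be tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MISSING_WHEN_ABSENT

_FLAT_TOL = 1e-12


@dataclass(frozen=True)
class ScalingFit:
    """One fitted model of mean metric value versus landscape side length."""

    metric: str
    class_code: int
    model: str  # "linear" | "power"
    intercept: float  # linear: intercept; power: prefactor a in a * L**b
    slope: float  # linear: slope; power: exponent b
    r2: float
    direction: str  # "increasing" | "decreasing" | "flat"


def mean_metric_by_extent(records: pd.DataFrame, metric: str,
                          class_code: int) -> pd.DataFrame:
    """Mean metric value per extent for one class.

    ``records`` is the long-format frame (absence rules already applied)
    with an ``extent_km`` column holding landscape side length in km.
    Zero-semantics metrics average over all landscapes including zeros;
    missing-semantics metrics (LSI) average over defined values only.
    Extents with no defined value are omitted with a warning.
    """
    sub = records[(records["metric"] == metric) & (records["class"] == class_code)]
    if metric in MISSING_WHEN_ABSENT:
        sub = sub[~sub["missing"]]
    rows = []
    for side, g in sub.groupby("extent_km"):
        rows.append((float(side), float(g["value"].mean())))
    all_extents = set(records["extent_km"].unique())
    got = {s for s, _ in rows}
    for s in sorted(all_extents - got):
        warnings.warn(
            f"{metric}/class {class_code}: no defined records at extent {s} km; omitted"
        )
    return pd.DataFrame(sorted(rows), columns=["side_km", "mean"])


def fit_scaling(table: pd.DataFrame, metric: str = "",
                class_code: int = -1) -> tuple[ScalingFit, ScalingFit | None]:
    """Fit linear and power-law models of mean vs. side length.

    Returns ``(linear_fit, power_fit)``; the power fit is ``None`` when any
    mean is non-positive (log undefined).  R-squared is computed on each
    model's own scale — raw for linear, log-log for power.
    """
    if len(table) < 3:
        raise ValueError("need means from at least 3 extents")
    x = table["side_km"].to_numpy(float)
    y = table["mean"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate: all extents equal")

    lin = stats.linregress(x, y)
    linear = ScalingFit(metric, class_code, "linear", float(lin.intercept),
                        float(lin.slope), float(lin.rvalue**2),
                        _direction(lin.slope))
    power = None
    if (y > 0).all():
        lp = stats.linregress(np.log(x), np.log(y))
        power = ScalingFit(metric, class_code, "power",
                           float(np.exp(lp.intercept)), float(lp.slope),
                           float(lp.rvalue**2), _direction(lp.slope))
    return linear, power


def _direction(slope: float) -> str:
    if abs(slope) < _FLAT_TOL:
        return "flat"
    return "increasing" if slope > 0 else "decreasing"


def best_fit(linear: ScalingFit, power: ScalingFit | None) -> ScalingFit:
    """The better of the two models; ties favour linear."""
    if power is None or power.r2 <= linear.r2:
        return linear
    return power


def classify_scale_invariant(fits_by_class: dict[int, tuple[ScalingFit, ScalingFit | None]],
                             r2_threshold: float = 0.98) -> tuple[str, str]:
    """Decide whether one metric scales predictably across classes.

    ``fits_by_class`` maps class code -> (linear fit, power fit or None).
    Predictable iff every class's best model reaches the threshold and all
    best-fit directions agree.  Returns ``(verdict, reason)`` where verdict
    is "predictable" or "unpredictable" and the reason names the failing
    class and rule.  Order of classes never affects the outcome.
    """
    best = {c: best_fit(lin, pow_) for c, (lin, pow_) in
            sorted(fits_by_class.items())}
    for c, f in best.items():
        if f.r2 < r2_threshold:
            return ("unpredictable",
                    f"class {c}: best R2 {f.r2:.4f} < {r2_threshold}")
    directions = {f.direction for f in best.values()}
    if len(directions) > 1:
        detail = ", ".join(f"class {c}: {f.direction}" for c, f in best.items())
        return "unpredictable", f"mixed directions ({detail})"
    return "predictable", "all classes fit one smooth form with one direction"


def scaling_report(records: pd.DataFrame, metrics, classes,
                   r2_threshold: float = 0.98) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fits and verdicts for every metric x class.

    Returns ``(fits, verdicts)`` DataFrames ready for CSV export.
    """
    fit_rows, verdict_rows = [], []
    for metric in metrics:
        fits_by_class = {}
        for code in classes:
            table = mean_metric_by_extent(records, metric, code)
            if len(table) < 3:
                continue
            lin, pow_ = fit_scaling(table, metric, code)
            fits_by_class[code] = (lin, pow_)
            for f in (lin, pow_):
                if f is not None:
                    fit_rows.append((metric, code, f.model, f.intercept,
                                     f.slope, f.r2, f.direction))
        if fits_by_class:
            verdict, reason = classify_scale_invariant(fits_by_class, r2_threshold)
            verdict_rows.append((metric, verdict, reason))
    fits = pd.DataFrame(fit_rows, columns=["metric", "class", "model",
                                           "intercept", "slope", "r2",
                                           "direction"])
    verdicts = pd.DataFrame(verdict_rows, columns=["metric", "verdict", "reason"])
    return fits, verdicts
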