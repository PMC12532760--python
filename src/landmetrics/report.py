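"""Figures summarising a pipeline run: scaling curves, yearly trends,
category frequencies and category maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES

_UNITS = {"CA": "km$^2$", "NP": "count", "TE": "km", "TCA": "km$^2$",
          "NDCA": "count", "LSI": ""}


def _require(out_dir: Path, name: str) -> pd.DataFrame:
    p = out_dir / name
    if not p.exists():
        raise FileNotFoundError(f"missing stage output: {name} (run the "
                                f"corresponding stage first)")
    df = pd.read_csv(p)
    if df.empty:
        raise ValueError(f"stage output {name} is empty")
    return df


def scaling_figure(out_dir) -> Path:
    """Six panels of mean metric value versus landscape side length, one
    line per class (log-log axes except LSI)."""
    out_dir = Path(out_dir)
    records = _require(out_dir, "metrics.csv")
    first_year = records["year"].min()
    sub = records[records["year"] == first_year]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, metric in zip(axes.ravel(), METRIC_NAMES):
        m = sub[sub["metric"] == metric]
        m = m[~m["missing"]]
        for code, g in m.groupby("class"):
            means = g.groupby("extent_km")["value"].mean()
            ax.plot(means.index, means.values, marker="o", label=f"class {code}")
        if metric != "LSI":
            ax.set_xscale("log")
            ax.set_yscale("log")
        ax.set_title(metric)
        ax.set_xlabel("landscape side (km)")
        ax.set_ylabel(_UNITS[metric])
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    path = out_dir / "fig_scaling.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def trends_figure(out_dir, extent_km: float | None = None) -> Path:
    """Mean metric value per year, one line per class, for one extent."""
    out_dir = Path(out_dir)
    trends = _require(out_dir, "trends.csv")
    if extent_km is None:
        extent_km = trends["extent_km"].min()
    sub = trends[trends["extent_km"] == extent_km]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, metric in zip(axes.ravel(), METRIC_NAMES):
        m = sub[sub["metric"] == metric]
        for code, g in m.groupby("class"):
            ax.plot(g["year"], g["mean"], label=f"class {code}")
        ax.set_title(f"{metric} ({extent_km:g} km landscapes)")
        ax.set_xlabel("year")
        ax.set_ylabel(_UNITS[metric])
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    path = out_dir / f"fig_trends_{extent_km:g}km.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def category_figure(out_dir) -> Path:
    """Bar chart of the nine CA/LSI category frequencies per class."""
    out_dir = Path(out_dir)
    freqs = _require(out_dir, "category_frequencies.csv")
    smallest = freqs["extent_km"].min()
    sub = freqs[freqs["extent_km"] == smallest]
    classes = sorted(sub["class"].unique())
    fig, axes = plt.subplots(1, len(classes), figsize=(3 * len(classes), 3.2),
                             squeeze=False)
    for ax, code in zip(axes[0], classes):
        g = sub[sub["class"] == code]
        ax.bar(g["category"], g["percent"])
        ax.set_title(f"class {code}")
        ax.tick_params(axis="x", rotation=90, labelsize=7)
        ax.set_ylabel("% of landscapes")
    fig.tight_layout()
    path = out_dir / "fig_categories.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def make_report(out_dir) -> list[Path]:
    """All figures plus a short textual summary; returns written paths."""
    out_dir = Path(out_dir)
    paths = [scaling_figure(out_dir), trends_figure(out_dir),
             category_figure(out_dir)]
    freqs = _require(out_dir, "category_frequencies.csv")
    verdicts = _require(out_dir, "scaling_verdicts.csv")
    lines = ["run summary", "===========", ""]
    lines.append("scale-predictability verdicts:")
    for _, v in verdicts.iterrows():
        lines.append(f"  {v['metric']}: {v['verdict']} ({v['reason']})")
    lines.append("")
    smallest = freqs["extent_km"].min()
    lines.append(f"dominant change category per class ({smallest:g} km landscapes):")
    sub = freqs[freqs["extent_km"] == smallest]
    for code, g in sub.groupby("class"):
        top = g.loc[g["percent"].idxmax()]
        lines.append(f"  class {code}: {top['category']} ({top['percent']:.2f}%)")
    summary = out_dir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    paths.append(summary)
    return paths
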