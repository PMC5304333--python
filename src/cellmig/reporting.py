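"""Headless figure generation with companion data tables.

Every figure kind (rose plot, plate heatmap, KDE panel, angular histogram,
boxplot panel) is produced in two stages: first a :class:`PlotSpec`
holding the complete underlying data as a tidy table plus axis/styling
settings, then a renderer that draws a matplotlib figure *only* from the
spec. Saving a spec writes PNG + SVG + the TSV table side by side, so any
figure can be regenerated — or re-plotted elsewhere — from its exported
table alone. Axis customisation lives in the spec's ``axes`` dict and
never touches the data values.

Series colors come from a fixed palette keyed by condition/replicate
order, mirroring plate-view color coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import matplotlib
from matplotlib.backends.backend_agg import FigureCanvasAgg  # noqa: F401 (Agg init)
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle

from . import migration_parameters as mp
from .statistics import plate_scores
from .track_io import Experiment

__all__ = [
    "PlotSpec",
    "rose_plot",
    "plate_heatmap",
    "render_distribution_panels",
    "render",
    "save",
    "PALETTE",
]

PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]

PLOT_KINDS = ("rose", "plate_heatmap", "kde", "angular_histogram", "boxplot")


@dataclass
class PlotSpec:
    """A figure's complete recipe: kind, data table, axes and styling."""

    kind: str
    data: pd.DataFrame
    axes: dict = field(default_factory=dict)
    styling: dict = field(default_factory=dict)
    title: str = ""

    def __post_init__(self):
        if self.kind not in PLOT_KINDS:
            raise ValueError(f"kind must be one of {PLOT_KINDS}")


# ---------------------------------------------------------------------------
# Spec builders
# ---------------------------------------------------------------------------


def rose_plot(
    exp: Experiment,
    shared_axes: bool = True,
    sample_size: int | None = None,
    seed: int | None = None,
) -> list[PlotSpec]:
    """One rose-plot spec per condition: recentered tracks from the origin.

    Replicate wells are pooled per condition. With ``shared_axes`` every
    panel gets the same symmetric limits (the maximum absolute recentered
    coordinate across all conditions), which is what makes conditions
    visually comparable at a glance. ``sample_size`` draws a reproducible
    random subset of tracks per condition.
    """
    per_cond: dict[str, pd.DataFrame] = {}
    for ci, cond in enumerate(exp.conditions):
        tracks = cond.tracks()
        if sample_size is not None:
            tracks = mp.subsample_tracks(
                tracks, sample_size,
                seed=None if seed is None else seed + ci)
        rows = []
        for t in mp.recenter_tracks(tracks):
            rows.append(pd.DataFrame({
                "condition": cond.name, "track_id": t.track_id,
                "time_index": t.frames, "x": t.x, "y": t.y,
            }))
        per_cond[cond.name] = (
            pd.concat(rows, ignore_index=True) if rows
            else pd.DataFrame(columns=["condition", "track_id",
                                       "time_index", "x", "y"]))

    limit = 1.0
    for tab in per_cond.values():
        if len(tab):
            limit = max(limit,
                        float(np.abs(tab[["x", "y"]].to_numpy()).max()))
    specs = []
    for ci, (name, tab) in enumerate(per_cond.items()):
        own = (float(np.abs(tab[["x", "y"]].to_numpy()).max())
               if len(tab) else 1.0)
        lim = limit if shared_axes else max(own, 1e-9)
        n_tracks = tab["track_id"].nunique()
        specs.append(PlotSpec(
            kind="rose", data=tab,
            axes={"xlim": (-lim, lim), "ylim": (-lim, lim)},
            styling={"color": PALETTE[ci % len(PALETTE)],
                     "n_tracks": int(n_tracks)},
            title=name,
        ))
    return specs


def plate_heatmap(
    exp: Experiment,
    metric: str = "median_speed",
    robust_z_base: str = "median_speed",
) -> PlotSpec:
    """Plate-geometry heatmap of a per-well metric; empty wells are missing.

    The data table carries one row per loaded well (row label, column,
    value); the color scale bounds are exported in ``axes``.
    """
    table = plate_scores(exp, metric=metric, robust_z_base=robust_z_base)
    data = table[["condition", "well", "row", "column", "value"]].copy()
    finite = data["value"].to_numpy()[np.isfinite(data["value"])]
    vmin = float(finite.min()) if len(finite) else 0.0
    vmax = float(finite.max()) if len(finite) else 1.0
    return PlotSpec(
        kind="plate_heatmap", data=data,
        axes={"n_rows": exp.plate_rows, "n_cols": exp.plate_columns,
              "vmin": vmin, "vmax": vmax},
        styling={"cmap": "viridis", "metric": metric},
        title=f"plate heatmap: {metric}",
    )


def render_distribution_panels(
    distributions: Sequence[mp.ParameterDistribution],
    kind: str,
    bin_width: float = 10.0,
    bandwidth: float | None = None,
    whisker_mode: str = "tukey",
) -> PlotSpec:
    """One panel with one series per distribution (replicate or condition).

    ``kind='kde'`` stores the evaluated density curves; ``'boxplot'`` and
    ``'angular_histogram'`` store the raw values / binned counts so the
    glyphs are recomputable from the table. Empty distributions are
    skipped with a warning.
    """
    import warnings

    if kind not in ("kde", "boxplot", "angular_histogram"):
        raise ValueError("kind must be 'kde', 'boxplot' or 'angular_histogram'")
    frames = []
    for dist in distributions:
        label = f"{dist.selection}" if dist.scope == "condition" else dist.selection
        if dist.n == 0:
            warnings.warn(f"empty distribution for {label!r}; panel skipped")
            continue
        if kind == "kde":
            grid, dens = mp.kde(dist.values, bandwidth=bandwidth)
            frames.append(pd.DataFrame(
                {"series": label, "grid": grid, "density": dens}))
        elif kind == "angular_histogram":
            hist = mp.angular_histogram(dist.values, bin_width=bin_width)
            hist.insert(0, "series", label)
            frames.append(hist)
        else:
            frames.append(pd.DataFrame(
                {"series": label, "value": dist.values}))
    if not frames:
        raise ValueError("all distributions empty; nothing to plot")
    data = pd.concat(frames, ignore_index=True)
    parameter = distributions[0].parameter
    return PlotSpec(
        kind=kind, data=data,
        axes={"xlabel": parameter},
        styling={"whisker_mode": whisker_mode, "bin_width": bin_width},
        title=f"{parameter} ({distributions[0].level})",
    )


# ---------------------------------------------------------------------------
# Renderers — figures are drawn from the spec's data table only
# ---------------------------------------------------------------------------


def _series_colors(names: Sequence[str]) -> dict[str, str]:
    return {n: PALETTE[i % len(PALETTE)] for i, n in enumerate(names)}


def render(spec: PlotSpec) -> Figure:
    """Draw the figure described by a spec (headless Agg figure)."""
    fig = Figure(figsize=spec.styling.get("figsize", (5, 4)), dpi=100)
    ax = fig.add_subplot(111)
    data = spec.data

    if spec.kind == "rose":
        color = spec.styling.get("color", PALETTE[0])
        for _, g in data.groupby("track_id", sort=False):
            ax.plot(g["x"], g["y"], color=color, lw=0.6, alpha=0.7)
        ax.set_xlim(spec.axes.get("xlim", (-1, 1)))
        ax.set_ylim(spec.axes.get("ylim", (-1, 1)))
        ax.set_aspect("equal")
        n = spec.styling.get("n_tracks", data["track_id"].nunique())
        ax.annotate(f"n = {n}", xy=(0.02, 0.95), xycoords="axes fraction")
        ax.set_xlabel("x"); ax.set_ylabel("y")

    elif spec.kind == "plate_heatmap":
        n_rows = int(spec.axes.get("n_rows", 8))
        n_cols = int(spec.axes.get("n_cols", 12))
        grid = np.full((n_rows, n_cols), np.nan)
        for _, r in data.iterrows():
            grid[ord(str(r["row"]).upper()) - 65, int(r["column"]) - 1] = r["value"]
        masked = np.ma.masked_invalid(grid)
        cmap = matplotlib.colormaps[spec.styling.get("cmap", "viridis")].copy()
        cmap.set_bad("#dddddd")
        im = ax.imshow(masked, cmap=cmap, vmin=spec.axes.get("vmin"),
                       vmax=spec.axes.get("vmax"), aspect="equal")
        ax.set_xticks(range(n_cols), [str(c + 1) for c in range(n_cols)])
        ax.set_yticks(range(n_rows), [chr(65 + r) for r in range(n_rows)])
        fig.colorbar(im, ax=ax, label=spec.styling.get("metric", "value"))

    elif spec.kind == "kde":
        colors = _series_colors(list(dict.fromkeys(data["series"])))
        for name, g in data.groupby("series", sort=False):
            ax.plot(g["grid"], g["density"], label=str(name),
                    color=colors[name])
        ax.set_ylabel("density")
        ax.set_xlabel(spec.axes.get("xlabel", "value"))
        ax.legend(fontsize=8)

    elif spec.kind == "angular_histogram":
        width = float(spec.styling.get("bin_width", 10.0))
        series = list(dict.fromkeys(data["series"]))
        colors = _series_colors(series)
        k = len(series)
        for i, name in enumerate(series):
            g = data[data["series"] == name]
            ax.bar(g["bin_start"] + width * (i + 0.5) / k, g["count"],
                   width=width / k, color=colors[name], label=str(name))
        ax.set_xlabel(spec.axes.get("xlabel", "turning angle (deg)"))
        ax.set_ylabel("count")
        ax.set_xlim(-180, 180)
        ax.legend(fontsize=8)

    elif spec.kind == "boxplot":
        series = list(dict.fromkeys(data["series"]))
        colors = _series_colors(series)
        mode = spec.styling.get("whisker_mode", "tukey")
        for i, name in enumerate(series):
            v = data.loc[data["series"] == name, "value"].to_numpy()
            st = mp.boxplot_stats(v, whisker_mode=mode)
            x = i + 1
            ax.add_patch(Rectangle((x - 0.3, st.q1), 0.6, st.q3 - st.q1,
                                   fill=True, alpha=0.4,
                                   facecolor=colors[name],
                                   edgecolor="black"))
            ax.plot([x - 0.3, x + 0.3], [st.median, st.median], color="black")
            ax.plot([x], [st.mean], marker="o", color="black", ms=3)
            ax.plot([x, x], [st.whisker_lo, st.q1], color="black", lw=0.8)
            ax.plot([x, x], [st.q3, st.whisker_hi], color="black", lw=0.8)
            if st.outliers:
                ax.plot([x] * len(st.outliers), st.outliers, ls="", marker=".",
                        color=colors[name])
            if st.far_outliers:
                ax.plot([x] * len(st.far_outliers), st.far_outliers, ls="",
                        marker="^", color=colors[name])
        ax.set_xticks(range(1, len(series) + 1), [str(s) for s in series],
                      fontsize=8)
        ax.set_ylabel(spec.axes.get("xlabel", "value"))

    ax.set_title(spec.title, fontsize=10)
    return fig


def save(spec: PlotSpec, out_dir, name: str) -> dict[str, Path]:
    """Write ``<name>.png``, ``<name>.svg`` and the data table ``<name>.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig = render(spec)
    paths = {}
    for ext in ("png", "svg"):
        p = out_dir / f"{name}.{ext}"
        fig.savefig(p, bbox_inches="tight")
        paths[ext] = p
    p = out_dir / f"{name}.tsv"
    spec.data.to_csv(p, sep="\t", index=False)
    paths["tsv"] = p
    return paths
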