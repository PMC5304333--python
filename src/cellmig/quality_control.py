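"""Minimal-motility quality control for tracked cells.

High-throughput tracking output always contains near-stationary artifacts:
dead cells, debris and segmentation noise that the tracker assigns a small
non-zero displacement (localisation jitter of the object centroid). Two
filters separate these from genuinely motile cells:

*Two-step filter.* Step-centric first: each step is labelled motile if its
displacement reaches a minimal translocation threshold. Trajectory-centric
second: a track is retained if at least a chosen fraction of its steps are
motile. Because only a fraction of steps must clear the threshold, cells
that pause during migration are still retained. Suggested starting points
from practice: threshold 0.1–0.5 µm for immune-like cells, 1.6–2 µm for
cancer-like cells, motile fraction 0.2–0.3. No preset is applied
automatically.

*Single-cutoff filter.* A track is retained if its median step
displacement reaches a threshold, applied globally across the experiment.
Simpler but stricter on pausing cells: a cell motile less than half the
time has a sub-threshold median and is discarded wholesale.

Both comparisons are inclusive (≥), so "30% motile steps" retains a track
with exactly 30%. Filters never mutate the experiment: they return reports
naming retained tracks, and the raw data stay analysable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .migration_parameters import step_table
from .track_io import Experiment, Trajectory

__all__ = [
    "TwoStepFilterParams",
    "FilterReport",
    "label_motile_steps",
    "two_step_filter",
    "single_cutoff_filter",
    "scan_thresholds",
    "reference_percentiles",
    "filter_experiment",
    "retained_track_ids",
]


@dataclass(frozen=True)
class TwoStepFilterParams:
    """Minimal translocation per step and required motile-step fraction."""

    step_threshold: float
    motile_fraction: float

    def __post_init__(self):
        if self.step_threshold < 0:
            raise ValueError("step_threshold must be >= 0")
        if not 0 <= self.motile_fraction <= 1:
            raise ValueError("motile_fraction must be in [0, 1]")


@dataclass
class FilterReport:
    """Retain/reject decision per track plus retention counts.

    ``per_track`` columns: track_id, n_steps, n_motile_steps,
    motile_fraction (NaN for the single-cutoff filter, which instead fills
    median_step_displacement), retained.
    """

    per_track: pd.DataFrame
    params: object
    method: str

    @property
    def n_initial(self) -> int:
        return len(self.per_track)

    @property
    def n_retained(self) -> int:
        return int(self.per_track["retained"].sum())

    @property
    def pct_retained(self) -> float:
        if self.n_initial == 0:
            return float("nan")
        return 100.0 * self.n_retained / self.n_initial

    def retained_ids(self) -> list:
        return self.per_track.loc[self.per_track["retained"], "track_id"].tolist()


def _step_lengths(traj: Trajectory) -> np.ndarray:
    return np.hypot(np.diff(traj.x), np.diff(traj.y))


def label_motile_steps(
    step_displacements: Sequence[float], step_threshold: float
) -> np.ndarray:
    """Boolean motility label per step: displacement ≥ threshold (inclusive)."""
    if step_threshold < 0:
        raise ValueError("step_threshold must be >= 0")
    return np.asarray(step_displacements, dtype=float) >= step_threshold


def two_step_filter(
    tracks: Iterable[Trajectory], params: TwoStepFilterParams
) -> FilterReport:
    """Retain tracks whose motile-step fraction reaches ``motile_fraction``.

    Zero-step tracks carry no motility evidence: they count in
    ``n_initial`` and are always rejected.
    """
    rows = []
    for traj in tracks:
        d = _step_lengths(traj)
        n = len(d)
        n_motile = int(label_motile_steps(d, params.step_threshold).sum())
        retained = n > 0 and (n_motile / n) >= params.motile_fraction
        rows.append({
            "track_id": traj.track_id, "n_steps": n,
            "n_motile_steps": n_motile,
            "motile_fraction": (n_motile / n) if n else float("nan"),
            "retained": retained,
        })
    per_track = pd.DataFrame(
        rows, columns=["track_id", "n_steps", "n_motile_steps",
                       "motile_fraction", "retained"])
    return FilterReport(per_track=per_track, params=params, method="two_step")


def single_cutoff_filter(
    tracks: Iterable[Trajectory], median_displacement_threshold: float
) -> FilterReport:
    """Retain tracks whose median step displacement ≥ threshold (inclusive)."""
    if median_displacement_threshold < 0:
        raise ValueError("threshold must be >= 0")
    rows = []
    for traj in tracks:
        d = _step_lengths(traj)
        n = len(d)
        med = float(np.median(d)) if n else float("nan")
        retained = n > 0 and med >= median_displacement_threshold
        rows.append({
            "track_id": traj.track_id, "n_steps": n,
            "median_step_displacement": med, "retained": retained,
        })
    per_track = pd.DataFrame(
        rows, columns=["track_id", "n_steps",
                       "median_step_displacement", "retained"])
    return FilterReport(per_track=per_track,
                        params=median_displacement_threshold,
                        method="single_cutoff")


def scan_thresholds(
    tracks: Sequence[Trajectory],
    step_threshold_grid: Sequence[float],
    motile_fraction: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step filter decisions over a grid of step thresholds.

    Returns the track × threshold retain matrix (booleans, columns named by
    threshold) and the per-threshold retention curve — the interactive
    threshold-selection view, as tables. The grid must be ascending;
    retention is then monotone non-increasing along it.
    """
    grid = list(step_threshold_grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly ascending")
    tracks = list(tracks)
    matrix = pd.DataFrame(
        {thr: two_step_filter(
            tracks, TwoStepFilterParams(thr, motile_fraction)
        ).per_track["retained"].to_numpy() for thr in grid},
        index=pd.Index([t.track_id for t in tracks], name="track_id"),
    )
    curve = pd.DataFrame({
        "step_threshold": grid,
        "n_retained": matrix.sum(axis=0).to_numpy(),
        "n_initial": len(tracks),
    })
    curve["pct_retained"] = 100.0 * curve["n_retained"] / max(len(tracks), 1)
    return matrix, curve


def reference_percentiles(exp: Experiment) -> pd.DataFrame:
    """Median and 5th percentile of pooled step displacements.

    One row per condition (replicates pooled) plus an ``experiment`` row
    pooling all conditions — the reference values shown to guide the
    choice of a step threshold.
    """
    rows = []
    all_d = []
    for cond in exp.conditions:
        tab = step_table(cond.tracks(), exp.frame_interval_min)
        d = tab["displacement"].to_numpy()
        if len(d) == 0:
            raise ValueError(f"condition {cond.name!r} has no steps")
        all_d.append(d)
        rows.append({
            "scope": "condition", "name": cond.name,
            "median_displacement": float(np.median(d)),
            "p5_displacement": float(np.percentile(d, 5)),
            "n_steps": len(d),
        })
    pooled = np.concatenate(all_d)
    rows.append({
        "scope": "experiment", "name": "all",
        "median_displacement": float(np.median(pooled)),
        "p5_displacement": float(np.percentile(pooled, 5)),
        "n_steps": len(pooled),
    })
    return pd.DataFrame(rows)


def filter_experiment(
    exp: Experiment,
    params: TwoStepFilterParams | float | Mapping[str, TwoStepFilterParams | float],
    method: str = "two_step",
) -> dict[str, FilterReport]:
    """Apply a filter per condition; parameters global or per-condition.

    ``params`` may be a single setting applied to every condition, or a
    mapping condition name → setting. Conditions are filtered
    independently: changing one condition's parameters never affects
    another's report. Returns one report per condition, pooling its
    replicate wells; track ids in the reports are ``well:track`` pairs so
    replicate provenance survives pooling.
    """
    if method not in ("two_step", "single_cutoff"):
        raise ValueError("method must be 'two_step' or 'single_cutoff'")
    reports = {}
    for cond in exp.conditions:
        p = params[cond.name] if isinstance(params, Mapping) else params
        tagged = [
            Trajectory(f"{w.label}:{t.track_id}", t.frames, t.x, t.y)
            for w in cond.wells for t in w.trajectories
        ]
        if method == "two_step":
            reports[cond.name] = two_step_filter(tagged, p)
        else:
            reports[cond.name] = single_cutoff_filter(tagged, float(p))
    return reports


def retained_track_ids(reports: Mapping[str, FilterReport]) -> set[tuple[str, str]]:
    """(well_label, track_id) pairs retained across all condition reports.

    The set plugs directly into
    :func:`cellmig.migration_parameters.collect_distribution`.
    """
    kept = set()
    for report in reports.values():
        for tid in report.retained_ids():
            well, _, track = str(tid).partition(":")
            kept.add((well, track))
    return kept


def summary_table(reports: Mapping[str, FilterReport]) -> pd.DataFrame:
    """Per-condition retention summary: parameters, initial and retained."""
    rows = []
    for name, rep in reports.items():
        rows.append({
            "condition": name, "method": rep.method,
            "params": repr(rep.params),
            "n_initial": rep.n_initial, "n_retained": rep.n_retained,
            "pct_retained": rep.pct_retained,
        })
    return pd.DataFrame(rows)


__all__.append("summary_table")
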