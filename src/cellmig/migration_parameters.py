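"""Step-centric and trajectory-centric migration parameters.

Given a track of positions :math:`(x_i, y_i)` at frame times :math:`t_i`,
each consecutive pair of recorded points defines a *step* with

* displacement  :math:`d_i = \\lVert p_{i} - p_{i-1} \\rVert` (Euclidean),
* duration      :math:`\\Delta t_i` in minutes (true frame gap × interval),
* speed         :math:`s_i = d_i / \\Delta t_i`,
* turning angle :math:`\\alpha_i` — the signed direction change between
  step :math:`i-1` and step :math:`i`, in degrees in (−180, 180], computed
  with the two-argument arctangent of the cross and dot products of the two
  step vectors. The first step of a track, and any step adjacent to a
  zero-length step, has no defined turning angle (NaN).

Per-trajectory aggregates follow the same conventions used across the
single-cell migration literature: cumulative path length
:math:`d_{tot} = \\sum_i d_i`; *track displacement* :math:`d_{tot}/N` with
:math:`N` the number of steps; net distance (straight line first → last
point); *track speed* :math:`d_{tot}` over elapsed time; and the end-point
directionality ratio (confinement ratio / meandering index)
:math:`ep\\_dr = \\text{net} / d_{tot} \\in [0, 1]`.

"Step-centric" statistics pool all steps regardless of track membership;
"trajectory-centric" statistics use one value per track. The two views are
complementary: trajectory-centric distributions resolve subpopulations of
cells that step-centric pooling averages away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .track_io import Condition, Experiment, Trajectory, Well

__all__ = [
    "StepMetrics",
    "TrackSummary",
    "ParameterDistribution",
    "BoxplotStats",
    "compute_step_metrics",
    "step_table",
    "summarize_track",
    "track_table",
    "collect_distribution",
    "recenter_tracks",
    "subsample_tracks",
    "silverman_bandwidth",
    "kde",
    "kde_mode_count",
    "angular_histogram",
    "boxplot_stats",
    "PARAMETERS",
    "LEVELS",
]

PARAMETERS = ("displacement", "speed", "turning_angle", "ep_dr")
LEVELS = ("step_centric", "trajectory_centric")


@dataclass(frozen=True)
class StepMetrics:
    """Metrics of one step of one track (angle is NaN when undefined)."""

    track_id: str
    step_index: int          # 1-based, step i joins point i-1 to point i
    displacement: float
    dt_min: float
    speed: float
    turn_angle_deg: float


@dataclass(frozen=True)
class TrackSummary:
    """Per-trajectory aggregates; degenerate (<2 points) tracks have NaNs."""

    track_id: str
    n_steps: int
    d_tot: float
    track_displacement: float   # d_tot / N
    net_distance: float
    track_speed: float          # d_tot / elapsed minutes
    ep_dr: float                # net / d_tot, 0 if d_tot == 0
    median_step_displacement: float
    degenerate: bool = False


def _step_vectors(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(dx, dy) for each consecutive pair of recorded points."""
    return np.diff(traj.x), np.diff(traj.y)


def turning_angles(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Signed direction change between successive step vectors, degrees.

    Element ``i`` is the angle from step ``i-1`` to step ``i``; element 0
    is NaN (no predecessor). Steps of zero length make both adjacent
    angles undefined. Result lies in (−180, 180]; a pure reversal is +180.
    """
    n = len(dx)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    ax, ay = dx[:-1], dy[:-1]
    bx, by = dx[1:], dy[1:]
    cross = ax * by - ay * bx
    dot = ax * bx + ay * by
    ang = np.degrees(np.arctan2(cross, dot))
    ang[ang == -180.0] = 180.0
    zero = (dx == 0) & (dy == 0)
    ang[zero[:-1] | zero[1:]] = np.nan
    out[1:] = ang
    return out


def compute_step_metrics(
    traj: Trajectory, frame_interval_min: float
) -> list[StepMetrics]:
    """Per-step displacement, duration, speed and turning angle.

    A track with fewer than two points yields an empty list. Steps spanning
    a tracking gap use the true elapsed time (frame gap × interval).
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    if traj.n_points < 2:
        return []
    dx, dy = _step_vectors(traj)
    d = np.hypot(dx, dy)
    dt = np.diff(traj.frames) * frame_interval_min
    if np.any(dt <= 0):
        raise ValueError(f"track {traj.track_id!r}: non-positive step duration")
    alpha = turning_angles(dx, dy)
    return [
        StepMetrics(traj.track_id, i + 1, float(d[i]), float(dt[i]),
                    float(d[i] / dt[i]), float(alpha[i]))
        for i in range(len(d))
    ]


def step_table(
    trajectories: Iterable[Trajectory], frame_interval_min: float
) -> pd.DataFrame:
    """Long-format table of all steps of all (≥2-point) tracks."""
    rows = []
    for traj in trajectories:
        rows.extend(compute_step_metrics(traj, frame_interval_min))
    return pd.DataFrame(
        rows,
        columns=["track_id", "step_index", "displacement", "dt_min",
                 "speed", "turn_angle_deg"],
    )


def summarize_track(traj: Trajectory, frame_interval_min: float) -> TrackSummary:
    """Trajectory-centric aggregates for one track.

    A single-point track is flagged degenerate: it is counted but carries
    no step statistics (all aggregates NaN).
    """
    if traj.n_points < 2:
        return TrackSummary(
            track_id=traj.track_id, n_steps=0, d_tot=math.nan,
            track_displacement=math.nan, net_distance=math.nan,
            track_speed=math.nan, ep_dr=math.nan,
            median_step_displacement=math.nan, degenerate=True,
        )
    dx, dy = _step_vectors(traj)
    d = np.hypot(dx, dy)
    n = len(d)
    d_tot = float(d.sum())
    net = float(math.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))
    elapsed = float((traj.frames[-1] - traj.frames[0]) * frame_interval_min)
    return TrackSummary(
        track_id=traj.track_id,
        n_steps=n,
        d_tot=d_tot,
        track_displacement=d_tot / n,
        net_distance=net,
        track_speed=d_tot / elapsed,
        ep_dr=(net / d_tot) if d_tot > 0 else 0.0,
        median_step_displacement=float(np.median(d)),
    )


def track_table(
    trajectories: Iterable[Trajectory], frame_interval_min: float
) -> pd.DataFrame:
    """Per-track summary table (one row per track, degenerate ones included)."""
    rows = [summarize_track(t, frame_interval_min) for t in trajectories]
    return pd.DataFrame(
        rows,
        columns=["track_id", "n_steps", "d_tot", "track_displacement",
                 "net_distance", "track_speed", "ep_dr",
                 "median_step_displacement", "degenerate"],
    )


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


@dataclass
class ParameterDistribution:
    """Pooled values of one parameter at one level and scope.

    ``provenance`` records, for each value, the well it came from so that
    condition-level pooling keeps per-replicate attribution.
    """

    parameter: str
    level: str
    scope: str              # "well" or "condition"
    selection: str          # well label or condition name
    values: np.ndarray
    provenance: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.values)

    def summary(self) -> dict:
        if self.n == 0:
            return {"n": 0, "mean": math.nan, "median": math.nan,
                    "q1": math.nan, "q3": math.nan,
                    "min": math.nan, "max": math.nan}
        v = self.values
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        return {"n": self.n, "mean": float(v.mean()), "median": float(med),
                "q1": float(q1), "q3": float(q3),
                "min": float(v.min()), "max": float(v.max())}


def _well_values(
    well: Well, parameter: str, level: str, frame_interval_min: float
) -> np.ndarray:
    if level == "step_centric":
        if parameter == "ep_dr":
            raise ValueError(
                "ep_dr is a whole-track quantity; no step-centric version exists"
            )
        tab = step_table(well.trajectories, frame_interval_min)
        if tab.empty:
            return np.empty(0)
        col = {"displacement": "displacement", "speed": "speed",
               "turning_angle": "turn_angle_deg"}[parameter]
        v = tab[col].to_numpy()
        return v[np.isfinite(v)]
    # trajectory-centric: one value per (non-degenerate) track
    out = []
    for traj in well.trajectories:
        s = summarize_track(traj, frame_interval_min)
        if s.degenerate:
            continue
        if parameter == "displacement":
            out.append(s.track_displacement)
        elif parameter == "speed":
            out.append(s.track_speed)
        elif parameter == "ep_dr":
            out.append(s.ep_dr)
        elif parameter == "turning_angle":
            # per-track mean absolute direction change (directionality proxy)
            a = np.array([m.turn_angle_deg for m in
                          compute_step_metrics(traj, frame_interval_min)])
            a = a[np.isfinite(a)]
            if len(a):
                out.append(float(np.abs(a).mean()))
        else:
            raise ValueError(f"unknown parameter {parameter!r}")
    return np.asarray(out, dtype=float)


def collect_distribution(
    exp: Experiment,
    parameter: str,
    level: str = "trajectory_centric",
    scope: str = "condition",
    selection: str | None = None,
    track_ids: set | None = None,
) -> ParameterDistribution:
    """Pool a migration parameter over a well or over a condition's replicates.

    ``track_ids``, when given, restricts pooling to tracks whose
    ``(well_label, track_id)`` pair is in the set — the hook by which
    quality-control filtering feeds into analysis without mutating data.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}")
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if scope not in ("well", "condition"):
        raise ValueError("scope must be 'well' or 'condition'")

    if scope == "well":
        pairs = [(c, w) for c, w in exp.wells() if w.label == selection]
        if not pairs:
            raise KeyError(f"well {selection!r} not in experiment")
    else:
        cond = exp.condition(selection) if selection else exp.conditions[0]
        pairs = [(cond, w) for w in cond.wells]

    values, prov = [], []
    for cond, well in pairs:
        w = well
        if track_ids is not None:
            kept = [t for t in well.trajectories
                    if (well.label, t.track_id) in track_ids]
            w = Well(row=well.row, column=well.column, trajectories=kept)
        v = _well_values(w, parameter, level, exp.frame_interval_min)
        values.append(v)
        prov.append(pd.DataFrame({
            "condition": cond.name, "well": well.label, "value": v,
        }))
    vals = np.concatenate(values) if values else np.empty(0)
    provenance = (pd.concat(prov, ignore_index=True) if prov
                  else pd.DataFrame(columns=["condition", "well", "value"]))
    return ParameterDistribution(
        parameter=parameter, level=level, scope=scope,
        selection=selection or pairs[0][0].name,
        values=vals, provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Track transforms
# ---------------------------------------------------------------------------


def recenter_tracks(trajectories: Iterable[Trajectory]) -> list[Trajectory]:
    """Translate each track so it starts at the origin (rose-plot view).

    Inter-point differences — and hence every step metric — are preserved
    exactly.
    """
    out = []
    for t in trajectories:
        out.append(Trajectory(t.track_id, t.frames, t.x - t.x[0], t.y - t.y[0]))
    return out


def subsample_tracks(
    trajectories: Sequence[Trajectory],
    sample_size: int,
    seed: int | np.random.Generator | None = None,
) -> list[Trajectory]:
    """Uniform random subset without replacement, reproducible under a seed.

    ``sample_size >= len(trajectories)`` returns all tracks (original order).
    """
    if sample_size < 0:
        raise ValueError("sample_size must be >= 0")
    trajectories = list(trajectories)
    if sample_size >= len(trajectories):
        return trajectories
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(trajectories), size=sample_size, replace=False)
    return [trajectories[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Distribution summaries: KDE, angular histogram, boxplot statistics
# ---------------------------------------------------------------------------


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 · min(sd, IQR/1.34) · n^{−1/5}."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(v) ** (-0.2)


def kde(
    values: Sequence[float],
    bandwidth: float | None = None,
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate on an even grid.

    The grid spans the data range extended by three bandwidths on each
    side, so the returned density integrates to 1 to within ~1e-3.
    Bandwidth defaults to Silverman's rule; pass a positive number (in data
    units) to override.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("kde needs at least 2 finite values")
    if v.std(ddof=1) == 0:
        raise ValueError(
            "kde undefined for zero-spread data; use a histogram instead"
        )
    h = silverman_bandwidth(v) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    k = sps.gaussian_kde(v, bw_method=h / v.std(ddof=1))
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, n_grid)
    return grid, k(grid)


def kde_mode_count(
    values: Sequence[float],
    bandwidth: float | None = None,
    min_rel_prominence: float = 0.05,
) -> int:
    """Number of substantive modes of the KDE of ``values``.

    A local maximum counts as a mode only if its prominence (height above
    the deepest dip separating it from a taller peak) reaches
    ``min_rel_prominence`` of the global density maximum. Sampling
    wiggles — tail ripples from isolated points, shoulder noise on a
    unimodal density — have near-zero prominence and are ignored; genuine
    subpopulation modes are separated by deep valleys and survive. Used to
    contrast trajectory-centric (subpopulation-resolving) with
    step-centric (pooled) displacement distributions.
    """
    from scipy.signal import find_peaks

    grid, dens = kde(values, bandwidth=bandwidth)
    peaks, _ = find_peaks(dens, prominence=min_rel_prominence * dens.max())
    return int(len(peaks))


def angular_histogram(
    angles_deg: Sequence[float], bin_width: float = 10.0
) -> pd.DataFrame:
    """Histogram of turning angles over (−180, 180] in fixed-width bins.

    Bins are half-open ``[start, start + width)``; the topmost bin also
    accepts +180 exactly. ``bin_width`` must divide 360. NaN angles
    (undefined turns) are dropped before counting.
    """
    if bin_width <= 0 or 360.0 % bin_width != 0:
        raise ValueError("bin_width must be a positive divisor of 360")
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if np.any((a <= -180.0) | (a > 180.0)):
        raise ValueError("angles must lie in (-180, 180]")
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(a, bins=edges)  # numpy closes the last bin
    return pd.DataFrame({"bin_start": edges[:-1], "count": counts})


@dataclass(frozen=True)
class BoxplotStats:
    median: float
    mean: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]
    far_outliers: tuple[float, ...]


def boxplot_stats(
    values: Sequence[float], whisker_mode: str = "tukey"
) -> BoxplotStats:
    """Five-number boxplot summary with outlier classification.

    Quartiles use linear interpolation. In the default ``tukey`` mode,
    values beyond 1.5×IQR from the quartiles are outliers and values
    beyond 3×IQR are far outliers; whiskers sit at the most extreme
    non-outlier values. ``minmax`` mode spans the whiskers over the full
    data range and flags nothing.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("boxplot_stats needs at least one finite value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    if whisker_mode == "minmax":
        return BoxplotStats(float(med), float(v.mean()), float(q1), float(q3),
                            float(v.min()), float(v.max()), (), ())
    if whisker_mode != "tukey":
        raise ValueError("whisker_mode must be 'tukey' or 'minmax'")
    iqr = q3 - q1
    lo_in, hi_in = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lo_far, hi_far = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    inliers = v[(v >= lo_in) & (v <= hi_in)]
    far = v[(v < lo_far) | (v > hi_far)]
    mild = v[((v < lo_in) | (v > hi_in)) & (v >= lo_far) & (v <= hi_far)]
    return BoxplotStats(
        median=float(med), mean=float(v.mean()), q1=float(q1), q3=float(q3),
        whisker_lo=float(inliers.min()), whisker_hi=float(inliers.max()),
        outliers=tuple(np.sort(mild)), far_outliers=tuple(np.sort(far)),
    )
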