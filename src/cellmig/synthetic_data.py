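"""Synthetic multiwell single-cell migration experiments with ground truth.

Two generative track models cover the phenomenology the analysis pipeline
has to distinguish:

*Motile cells* follow a persistent random walk (PRW): the heading evolves
as θ_{i+1} = θ_i + η with η ~ Normal(0, turn_sd), and each step length is
drawn from a Normal(mean, sd) truncated at zero. Small turning noise gives
directionally persistent, ballistic-looking tracks; large noise gives
diffusive ones. Cell pausing is emulated by a per-frame pause probability:
a paused frame replaces the motile step with pure localisation jitter.
Heterogeneous populations are built from mixtures of PRW specs, optionally
with between-track variation of the mean step length.

*Stationary artifacts* (dead cells, debris, segmentation noise) are a
fixed point plus isotropic Gaussian localisation jitter per frame — the
mechanism by which trackers assign non-zero displacement to non-moving
objects. Each step is then a difference of two jitters, so step
displacements are Rayleigh(σ√2) with mean σ√π, and the net displacement
stays bounded in probability however long the track runs.

Everything is deterministic under a master seed, with hierarchical
sub-seeding per well and per track, so replicate wells are independent
draws yet the whole experiment is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .track_io import (
    Condition,
    Experiment,
    Trajectory,
    Well,
    parse_well_label,
    write_tracks_file,
)

__all__ = [
    "PopulationSpec",
    "GroundTruth",
    "simulate_prw_track",
    "simulate_artifact_track",
    "simulate_condition_tracks",
    "simulate_experiment",
    "simulate_track_speeds",
    "DEFAULT_MOTILE",
    "DEFAULT_ARTIFACT",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of one track population within a condition.

    Lengths are in the experiment's length unit (µm by default). For
    ``kind='motile_prw'``: ``mean_step_length``/``step_length_sd`` set the
    within-track step-length distribution (Normal truncated at 0),
    ``between_track_sd`` spreads each track's own mean step length around
    the population mean, ``turn_sd_deg`` controls persistence and
    ``pause_probability`` the per-frame chance of pausing (a paused frame
    contributes only localisation jitter). For ``kind='stationary_artifact'``
    only ``artifact_jitter_sd`` matters.
    """

    name: str = "population"
    kind: str = "motile_prw"
    n_tracks: int = 50
    n_frames: int = 61
    mean_step_length: float = 2.0
    step_length_sd: float = 0.5
    between_track_sd: float = 0.0
    turn_sd_deg: float = 30.0
    pause_probability: float = 0.0
    artifact_jitter_sd: float = 0.05

    def __post_init__(self):
        if self.kind not in ("motile_prw", "stationary_artifact"):
            raise ValueError(f"unknown population kind {self.kind!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be >= 0")
        for attr in ("mean_step_length", "step_length_sd", "between_track_sd",
                     "turn_sd_deg", "artifact_jitter_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if not 0 <= self.pause_probability <= 1:
            raise ValueError("pause_probability must be in [0, 1]")


# realistic defaults: a cancer-like motile population imaged at 96-well
# throughput, and centroid jitter well below one pixel
DEFAULT_MOTILE = PopulationSpec(name="motile", kind="motile_prw")
DEFAULT_ARTIFACT = PopulationSpec(name="artifact", kind="stationary_artifact",
                                  artifact_jitter_sd=0.05)


@dataclass
class GroundTruth:
    """Per-track labels and the population specs that generated them."""

    labels: pd.DataFrame       # condition, well, track_id, population, kind
    populations: dict[str, list[PopulationSpec]]
    effects: dict[str, float]

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.labels.to_csv(path, sep="\t", index=False)
        return path


def _truncated_normal(mean, sd, size, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 by rejection (vectorised)."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size=size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < 0
    return out


def simulate_prw_track(
    spec: PopulationSpec,
    rng: np.random.Generator,
    track_id: str = "1",
    start: tuple[float, float] = (0.0, 0.0),
    speed_multiplier: float = 1.0,
) -> Trajectory:
    """Draw one persistent-random-walk track.

    With ``turn_sd_deg = 0`` and ``step_length_sd = 0`` the track is
    perfectly straight (end-point directionality ratio 1).
    """
    n_steps = spec.n_frames - 1
    track_mean = spec.mean_step_length
    if spec.between_track_sd > 0:
        track_mean = max(0.0, rng.normal(track_mean, spec.between_track_sd))
    lengths = _truncated_normal(track_mean * speed_multiplier,
                                spec.step_length_sd * speed_multiplier,
                                n_steps, rng)
    theta = rng.uniform(0, 2 * math.pi) + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, math.radians(spec.turn_sd_deg),
                                     n_steps - 1))]
    )
    dx = lengths * np.cos(theta)
    dy = lengths * np.sin(theta)
    if spec.pause_probability > 0:
        paused = rng.random(n_steps) < spec.pause_probability
        jit = spec.artifact_jitter_sd
        dx[paused] = rng.normal(0.0, jit, int(paused.sum()))
        dy[paused] = rng.normal(0.0, jit, int(paused.sum()))
    x = start[0] + np.concatenate([[0.0], np.cumsum(dx)])
    y = start[1] + np.concatenate([[0.0], np.cumsum(dy)])
    return Trajectory(track_id, np.arange(spec.n_frames), x, y)


def simulate_artifact_track(
    spec: PopulationSpec,
    rng: np.random.Generator,
    track_id: str = "1",
    start: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Draw one stationary-artifact track: fixed point + Gaussian jitter.

    Positions are iid around the anchor, so each step displacement is
    Rayleigh with scale σ√2 (mean σ√π) and the net displacement does not
    grow with track length.
    """
    x = start[0] + rng.normal(0.0, spec.artifact_jitter_sd, spec.n_frames)
    y = start[1] + rng.normal(0.0, spec.artifact_jitter_sd, spec.n_frames)
    return Trajectory(track_id, np.arange(spec.n_frames), x, y)


def simulate_condition_tracks(
    populations: Sequence[PopulationSpec],
    rng: np.random.Generator,
    speed_multiplier: float = 1.0,
    field_size: float = 500.0,
) -> tuple[list[Trajectory], list[tuple[str, str]]]:
    """Tracks for one well: all populations, labelled, ids unique in-well."""
    tracks, labels = [], []
    counter = 0
    for pop in populations:
        for _ in range(pop.n_tracks):
            counter += 1
            tid = str(counter)
            start = tuple(rng.uniform(0, field_size, 2))
            if pop.kind == "motile_prw":
                t = simulate_prw_track(pop, rng, tid, start, speed_multiplier)
            else:
                t = simulate_artifact_track(pop, rng, tid, start)
            tracks.append(t)
            labels.append((pop.name, pop.kind))
    return tracks, labels


def simulate_experiment(
    layout: Mapping,
    populations: Mapping[str, Sequence[PopulationSpec]],
    effects: Mapping[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
    out_dir: Path | str | None = None,
) -> tuple[Experiment, GroundTruth]:
    """Simulate a multiwell experiment, optionally writing it to disk.

    ``layout`` uses the plate-layout schema of :mod:`cellmig.track_io`
    (conditions → replicate wells, frame interval, units). ``populations``
    maps each condition name to its track populations; ``effects`` maps
    condition names to a speed multiplier applied to its motile
    populations (treatment effect on step length, hence speed).

    Replicate wells are independent draws from the same specs. With
    ``out_dir`` set, per-well four-column track files (``<well>.txt``),
    the layout (``layout.yaml``) and the ground-truth labels
    (``ground_truth.tsv``) are written, forming a complete on-disk
    experiment that round-trips through the reader.
    """
    effects = dict(effects or {})
    plate = layout.get("plate") or {}
    n_rows, n_cols = int(plate.get("rows", 8)), int(plate.get("columns", 12))
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))

    cond_specs = layout["conditions"]
    well_labels_all = [str(w) for c in cond_specs for w in c["wells"]]
    if len(well_labels_all) != len(set(well_labels_all)):
        raise ValueError("overlapping well assignments in layout")

    child_seeds = iter(ss.spawn(len(well_labels_all)))
    conditions, label_rows = [], []
    for cspec in cond_specs:
        name = cspec["name"]
        if name not in populations:
            raise ValueError(f"no populations given for condition {name!r}")
        mult = float(effects.get(name, 1.0))
        wells = []
        for lab in cspec["wells"]:
            row, col = parse_well_label(str(lab))
            rng = np.random.default_rng(next(child_seeds))
            tracks, labels = simulate_condition_tracks(
                populations[name], rng, speed_multiplier=mult)
            wells.append(Well(row=row, column=col, trajectories=tracks))
            label_rows.extend(
                {"condition": name, "well": f"{row}{col}", "track_id": t.track_id,
                 "population": pop_name, "kind": kind}
                for t, (pop_name, kind) in zip(tracks, labels)
            )
        conditions.append(Condition(name=name,
                                    treatment=str(cspec.get("treatment", "")),
                                    wells=wells))

    exp = Experiment(
        conditions=conditions,
        frame_interval_min=float(layout["frame_interval_min"]),
        length_unit=str(layout.get("length_unit", "micron")),
        pixel_size_um=(float(layout["pixel_size_um"])
                       if layout.get("pixel_size_um") else None),
        plate_rows=n_rows, plate_columns=n_cols,
    )
    truth = GroundTruth(
        labels=pd.DataFrame(label_rows, columns=["condition", "well", "track_id",
                                                 "population", "kind"]),
        populations={k: list(v) for k, v in populations.items()},
        effects=effects,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for _, well in exp.wells():
            write_tracks_file(well.trajectories, out_dir / f"{well.label}.txt")
        with (out_dir / "layout.yaml").open("w") as fh:
            yaml.safe_dump(dict(layout), fh, sort_keys=False)
        truth.write(out_dir / "ground_truth.tsv")
    return exp, truth


def simulate_track_speeds(
    n_repeats: int,
    n_tracks: int,
    spec: PopulationSpec,
    rng: np.random.Generator,
    speed_multiplier: float = 1.0,
    frame_interval_min: float = 1.0,
) -> np.ndarray:
    """(n_repeats, n_tracks) matrix of PRW track speeds, fully vectorised.

    A PRW track's speed, d_tot over elapsed time, is the mean of its step
    lengths divided by the frame interval — headings cancel out of the
    path length — so speeds can be drawn directly from the step-length
    distribution. This is the exact track-speed law of
    :func:`simulate_prw_track` (pause probability 0, no between-track
    spread), and is what makes large calibration studies (type-I error,
    power) affordable.
    """
    n_steps = spec.n_frames - 1
    lengths = _truncated_normal(
        spec.mean_step_length * speed_multiplier,
        spec.step_length_sd * speed_multiplier,
        (n_repeats, n_tracks, n_steps), rng,
    )
    return lengths.mean(axis=2) / frame_interval_min
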