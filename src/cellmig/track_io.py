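"""Reading, validation and writing of single-cell tracking data.

The on-disk interchange format is the four-column delimited text file most
tracking tools can export: one row per detected cell position, with columns

    track_id    time_index    x    y

where ``time_index`` is an integer frame number and ``x``/``y`` are
coordinates in pixels or micrometres. One file holds the tracks of one well
of a multiwell plate; an experiment is a plate layout mapping wells to
biological conditions plus acquisition metadata (frame interval, pixel
size, length unit).

Delimiters (tab, comma, semicolon) and an optional single header line are
auto-detected; both can also be forced. Coordinates are stored exactly as
given (image convention, y axis typically pointing down): every downstream
parameter is either invariant or sign-covariant under reflection, so no
axis flip is applied.
"""

from __future__ import annotations

import csv
import io
import math
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import yaml

__all__ = [
    "TrackIOError",
    "TrackParseError",
    "TrackValidationError",
    "LayoutError",
    "TrackPoint",
    "Trajectory",
    "Well",
    "Condition",
    "Experiment",
    "read_tracks_file",
    "write_tracks_file",
    "convert_to_micron",
    "experiment_to_micron",
    "split_at_gaps",
    "parse_well_label",
    "well_label",
    "load_layout",
    "assemble_experiment",
    "experiment_manifest",
]

_DELIMITERS = ("\t", ",", ";")


class TrackIOError(ValueError):
    """Base class for track I/O failures."""


class TrackParseError(TrackIOError):
    """A row of a track file could not be parsed; carries the line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class TrackValidationError(TrackIOError):
    """Parsed data violate a structural invariant (e.g. duplicate times)."""


class LayoutError(TrackIOError):
    """The plate layout configuration is inconsistent or incomplete."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class TrackPoint(NamedTuple):
    """One recorded cell position: frame number, minutes, x, y."""

    time_index: int
    time_min: float
    x: float
    y: float


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered 2D positions of one tracked cell.

    ``frames`` are strictly increasing integer frame indices; ``x``/``y``
    are finite coordinates in the experiment's length unit. Single-point
    trajectories are legal (they count as tracks but contribute no steps).
    """

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(frames) == len(x) == len(y)):
            raise TrackValidationError(
                f"track {self.track_id!r}: frames/x/y lengths differ"
            )
        if len(frames) == 0:
            raise TrackValidationError(f"track {self.track_id!r}: no points")
        if np.any(frames < 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: negative time index"
            )
        d = np.diff(frames)
        if np.any(d == 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: duplicate time index"
            )
        if np.any(d < 0):
            # callers normally sort before constructing; be strict here
            raise TrackValidationError(
                f"track {self.track_id!r}: time indices not increasing"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite coordinate"
            )
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1

    def points(self, frame_interval_min: float = 1.0) -> list[TrackPoint]:
        """Materialise the track as ``TrackPoint`` rows (minutes derived)."""
        return [
            TrackPoint(int(f), float(f) * frame_interval_min, float(px), float(py))
            for f, px, py in zip(self.frames, self.x, self.y)
        ]

    def positions(self) -> np.ndarray:
        """(n, 2) array of coordinates."""
        return np.column_stack([self.x, self.y])


@dataclass
class Well:
    """One well of the plate: position, tracks, optional processing tags."""

    row: str
    column: int
    trajectories: list[Trajectory] = field(default_factory=list)
    algorithm_tag: str = ""
    imaging_tag: str = ""

    def __post_init__(self):
        ids = [t.track_id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise TrackValidationError(
                f"well {self.label}: duplicate track ids"
            )

    @property
    def label(self) -> str:
        return f"{self.row}{self.column}"

    @property
    def n_tracks(self) -> int:
        return len(self.trajectories)


@dataclass
class Condition:
    """A biological condition assayed in one or more replicate wells."""

    name: str
    wells: list[Well]
    treatment: str = ""

    def __post_init__(self):
        if not self.wells:
            raise TrackValidationError(
                f"condition {self.name!r}: needs at least one replicate well"
            )

    def tracks(self) -> list[Trajectory]:
        """All tracks pooled across replicate wells."""
        return [t for w in self.wells for t in w.trajectories]


@dataclass
class Experiment:
    """A plate of conditions plus acquisition metadata."""

    conditions: list[Condition]
    frame_interval_min: float
    length_unit: str = "micron"
    pixel_size_um: float | None = None
    plate_rows: int = 8
    plate_columns: int = 12

    def __post_init__(self):
        if self.frame_interval_min <= 0:
            raise TrackValidationError("frame_interval_min must be > 0")
        if self.length_unit not in ("pixel", "micron"):
            raise TrackValidationError(
                f"length_unit must be 'pixel' or 'micron', got {self.length_unit!r}"
            )
        if self.length_unit == "pixel":
            if self.pixel_size_um is None or self.pixel_size_um <= 0:
                raise TrackValidationError(
                    "pixel_size_um must be > 0 when coordinates are in pixels"
                )
        labels = [w.label for c in self.conditions for w in c.wells]
        if len(labels) != len(set(labels)):
            raise TrackValidationError("well assigned to more than one condition")

    def wells(self) -> Iterator[tuple[Condition, Well]]:
        for c in self.conditions:
            for w in c.wells:
                yield c, w

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def condition_names(self) -> list[str]:
        return [c.name for c in self.conditions]


# ---------------------------------------------------------------------------
# Reading and writing the four-column format
# ---------------------------------------------------------------------------


def _sniff(sample_lines: list[str]) -> tuple[str, bool]:
    """Detect delimiter and presence of a single header line."""
    counts = {d: sum(line.count(d) for line in sample_lines) for d in _DELIMITERS}
    delimiter = max(counts, key=counts.get)
    if counts[delimiter] == 0:
        raise TrackIOError(
            "could not detect delimiter (expected tab, comma or semicolon)"
        )
    first = sample_lines[0].rstrip("\n").split(delimiter)
    has_header = False
    if len(first) >= 2:
        try:
            float(first[1])
        except ValueError:
            has_header = True
    return delimiter, has_header


def _parse_row(row: Sequence[str], path, lineno: int) -> tuple[str, int, float, float]:
    if len(row) != 4:
        raise TrackParseError(
            path, lineno, f"expected 4 columns, found {len(row)}"
        )
    tid = row[0].strip()
    try:
        t_raw = float(row[1])
    except ValueError:
        raise TrackParseError(path, lineno, f"unparseable time {row[1]!r}") from None
    if t_raw != int(t_raw):
        raise TrackParseError(path, lineno, f"time index {row[1]!r} is not an integer")
    try:
        x = float(row[2])
        y = float(row[3])
    except ValueError:
        raise TrackParseError(
            path, lineno, f"unparseable coordinate in {row!r}"
        ) from None
    if not (math.isfinite(x) and math.isfinite(y)):
        raise TrackParseError(path, lineno, "non-finite coordinate")
    return tid, int(t_raw), x, y


def read_tracks_file(
    path,
    *,
    delimiter: str | None = None,
    has_header: bool | None = None,
) -> list[Trajectory]:
    """Read one well's tracks from a four-column delimited text file.

    Rows are grouped by track id and sorted by time; the file itself need
    not be sorted. Trajectories are returned in order of first appearance
    of their id. An empty file yields an empty list.

    Raises
    ------
    TrackParseError
        for a malformed row (message carries the 1-based line number).
    TrackValidationError
        for duplicate (id, time_index) pairs.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines()]
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        return []
    if delimiter is None or has_header is None:
        sniff_delim, sniff_header = _sniff([ln for _, ln in content[:20]])
        delimiter = delimiter if delimiter is not None else sniff_delim
        has_header = has_header if has_header is not None else sniff_header
    if has_header:
        content = content[1:]

    seen: dict[tuple[str, int], int] = {}
    groups: dict[str, list[tuple[int, float, float]]] = {}
    for lineno, line in content:
        row = next(csv.reader(io.StringIO(line), delimiter=delimiter))
        tid, t, x, y = _parse_row(row, path, lineno)
        key = (tid, t)
        if key in seen:
            raise TrackValidationError(
                f"{path}:{lineno}: duplicate time index {t} for track {tid!r} "
                f"(first seen line {seen[key]})"
            )
        seen[key] = lineno
        groups.setdefault(tid, []).append((t, x, y))

    trajectories = []
    for tid, pts in groups.items():
        pts.sort(key=lambda p: p[0])
        arr = np.array(pts, dtype=float)
        trajectories.append(
            Trajectory(tid, arr[:, 0].astype(np.int64), arr[:, 1], arr[:, 2])
        )
    return trajectories


def write_tracks_file(
    trajectories: Iterable[Trajectory],
    path,
    *,
    delimiter: str = "\t",
    header: bool = True,
) -> Path:
    """Write tracks in the canonical four-column format.

    Coordinates are written with ``repr`` precision so that a write/read
    round trip reproduces the data bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        if header:
            fh.write(delimiter.join(["track_id", "time_index", "x", "y"]) + "\n")
        for traj in trajectories:
            for f, x, y in zip(traj.frames, traj.x, traj.y):
                fh.write(
                    delimiter.join([str(traj.track_id), str(int(f)),
                                    repr(float(x)), repr(float(y))]) + "\n"
                )
    return path


def convert_to_micron(traj: Trajectory, pixel_size_um: float) -> Trajectory:
    """Scale pixel coordinates to micrometres; time is untouched."""
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return replace(traj, x=traj.x * pixel_size_um, y=traj.y * pixel_size_um)


def experiment_to_micron(exp: Experiment) -> Experiment:
    """Return a copy of the experiment with all coordinates in µm."""
    if exp.length_unit == "micron":
        return exp
    scale = exp.pixel_size_um
    conditions = [
        Condition(
            name=c.name,
            treatment=c.treatment,
            wells=[
                Well(
                    row=w.row,
                    column=w.column,
                    trajectories=[convert_to_micron(t, scale) for t in w.trajectories],
                    algorithm_tag=w.algorithm_tag,
                    imaging_tag=w.imaging_tag,
                )
                for w in c.wells
            ],
        )
        for c in exp.conditions
    ]
    return Experiment(
        conditions=conditions,
        frame_interval_min=exp.frame_interval_min,
        length_unit="micron",
        pixel_size_um=None,
        plate_rows=exp.plate_rows,
        plate_columns=exp.plate_columns,
    )


def split_at_gaps(traj: Trajectory, max_gap_frames: int) -> list[Trajectory]:
    """Split a track wherever consecutive frames are more than
    ``max_gap_frames`` apart; fragments keep the parent id with a suffix.

    By default tracks are analysed unsplit, with steps spanning gaps using
    the true Δt; this helper is for users who prefer contiguous fragments.
    """
    if max_gap_frames < 1:
        raise ValueError("max_gap_frames must be >= 1")
    gaps = np.diff(traj.frames)
    cut = np.nonzero(gaps > max_gap_frames)[0] + 1
    if len(cut) == 0:
        return [traj]
    pieces = []
    for k, idx in enumerate(np.split(np.arange(len(traj)), cut)):
        pieces.append(
            Trajectory(
                f"{traj.track_id}.{k}", traj.frames[idx], traj.x[idx], traj.y[idx]
            )
        )
    return pieces


# ---------------------------------------------------------------------------
# Plate layout and experiment assembly
# ---------------------------------------------------------------------------

_ROW_LETTERS = string.ascii_uppercase


def parse_well_label(label: str) -> tuple[str, int]:
    """Split a well label like ``"A1"`` or ``"H12"`` into (row, column)."""
    label = label.strip().upper()
    if not label or label[0] not in _ROW_LETTERS or not label[1:].isdigit():
        raise LayoutError(f"malformed well label {label!r}")
    return label[0], int(label[1:])


def well_label(row: str, column: int) -> str:
    return f"{row}{column}"


_LAYOUT_KEYS = {
    "plate",
    "frame_interval_min",
    "length_unit",
    "pixel_size_um",
    "conditions",
}


def load_layout(path) -> dict:
    """Load and minimally validate a YAML plate-layout configuration.

    Schema::

        plate: {rows: 8, columns: 12}        # optional, default 96-well
        frame_interval_min: 1.5
        length_unit: pixel | micron
        pixel_size_um: 0.64                  # required when unit is pixel
        conditions:
          - name: control
            treatment: none                  # optional free text
            wells: [A1, A2]
    """
    with open(path) as fh:
        layout = yaml.safe_load(fh)
    if not isinstance(layout, dict):
        raise LayoutError("layout file must contain a mapping")
    unknown = set(layout) - _LAYOUT_KEYS
    if unknown:
        raise LayoutError(f"unknown layout keys: {sorted(unknown)}")
    for key in ("frame_interval_min", "conditions"):
        if key not in layout:
            raise LayoutError(f"layout missing required key {key!r}")
    return layout


def assemble_experiment(
    layout: Mapping,
    files: Mapping[str, Path | str],
    *,
    allow_missing: bool = False,
) -> Experiment:
    """Build an :class:`Experiment` from a layout mapping and per-well files.

    ``files`` maps well labels (``"A1"``) to four-column track files. Every
    well named in the layout must have a file unless ``allow_missing`` is
    set, in which case absent wells are loaded empty.
    """
    plate = layout.get("plate") or {}
    n_rows = int(plate.get("rows", 8))
    n_cols = int(plate.get("columns", 12))
    files = {k.strip().upper(): v for k, v in files.items()}

    conditions = []
    for cspec in layout["conditions"]:
        name = cspec["name"]
        well_labels = cspec.get("wells", [])
        if not well_labels:
            raise LayoutError(f"condition {name!r} lists no wells")
        wells = []
        for lab in well_labels:
            row, col = parse_well_label(str(lab))
            if _ROW_LETTERS.index(row) >= n_rows or not (1 <= col <= n_cols):
                raise LayoutError(
                    f"well {lab} outside {n_rows}x{n_cols} plate"
                )
            key = well_label(row, col)
            if key in files:
                trajectories = read_tracks_file(files[key])
            elif allow_missing:
                trajectories = []
            else:
                raise LayoutError(
                    f"no track file for well {key} (condition {name!r})"
                )
            wells.append(Well(row=row, column=col, trajectories=trajectories))
        conditions.append(
            Condition(name=name, treatment=str(cspec.get("treatment", "")), wells=wells)
        )

    return Experiment(
        conditions=conditions,
        frame_interval_min=float(layout["frame_interval_min"]),
        length_unit=str(layout.get("length_unit", "micron")),
        pixel_size_um=(
            float(layout["pixel_size_um"]) if layout.get("pixel_size_um") else None
        ),
        plate_rows=n_rows,
        plate_columns=n_cols,
    )


def experiment_manifest(exp: Experiment):
    """Per-well manifest: condition, treatment, well, number of tracks."""
    import pandas as pd

    rows = [
        {
            "condition": c.name,
            "treatment": c.treatment,
            "well": w.label,
            "n_tracks": w.n_tracks,
        }
        for c, w in exp.wells()
    ]
    return pd.DataFrame(rows, columns=["condition", "treatment", "well", "n_tracks"])
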