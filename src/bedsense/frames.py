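"""Sensor geometry, pressure frames, and the frame-stream file format.

The mattress exposes 30 binary (on/off) pressure sensing areas sampled at a
nominal 1 Hz. This module defines the in-memory containers for that signal
(:class:`SensorGrid`, :class:`PressureFrame`, :class:`FrameStream`) and a
plain-text stream format: one row per second, an ISO-8601 timestamp followed
by 30 comma-separated ``0``/``1`` fields. Everything downstream (posture,
sleep, norms, dashboard) consumes :class:`FrameStream` only.

The physical arrangement of the 30 areas is not dictated by the hardware
abstraction; the default convention is 10 rows (head to foot) by 3 columns
(left, centre, right), area ids row-major 1..30. The geometry is configurable
and only the simulator's posture templates depend on it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np

#: Number of binary sensing areas in the mattress foam.
N_AREAS = 30


class FrameFormatError(ValueError):
    """A row of a frame file could not be parsed (carries the line number)."""


class StreamValidationError(ValueError):
    """A frame stream violates its contract (e.g. duplicate timestamps)."""


@dataclass(frozen=True)
class SensorGrid:
    """Spatial convention for the 30 sensing areas.

    Parameters
    ----------
    rows, cols
        Grid shape; ``rows * cols`` must equal 30. Rows run head to foot,
        columns left to right. Area ids are row-major 1..30.
    """

    rows: int = 10
    cols: int = 3

    def __post_init__(self) -> None:
        if self.rows * self.cols != N_AREAS:
            raise ValueError(
                f"grid must cover exactly {N_AREAS} areas, got {self.rows}x{self.cols}"
            )

    @property
    def n_areas(self) -> int:
        return N_AREAS

    @property
    def area_ids(self) -> np.ndarray:
        """Area identifiers 1..30, row-major."""
        return np.arange(1, N_AREAS + 1)

    def index(self, row: int, col: int) -> int:
        """Flat 0-based index of the area at (row, col)."""
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"({row}, {col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col

    def to_matrix(self, states: Sequence[bool]) -> np.ndarray:
        """Reshape a 30-element state vector to the grid layout."""
        a = np.asarray(states, dtype=bool)
        if a.shape != (N_AREAS,):
            raise ValueError(f"expected {N_AREAS} states, got {a.shape}")
        return a.reshape(self.rows, self.cols)


DEFAULT_GRID = SensorGrid()


def _as_states(states: Sequence[bool]) -> np.ndarray:
    a = np.asarray(states)
    if a.shape != (N_AREAS,):
        raise ValueError(f"a frame has exactly {N_AREAS} states, got shape {a.shape}")
    return a.astype(bool)


@dataclass(frozen=True)
class PressureFrame:
    """One 1 Hz snapshot: a timestamp and 30 boolean area states."""

    timestamp: np.datetime64
    states: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", np.datetime64(self.timestamp, "s"))
        object.__setattr__(self, "states", _as_states(self.states))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PressureFrame):
            return NotImplemented
        return self.timestamp == other.timestamp and bool(
            np.array_equal(self.states, other.states)
        )


@dataclass
class FrameStream:
    """A time-ordered sequence of frames for one resident.

    ``timestamps`` is a ``datetime64[s]`` array, strictly increasing;
    ``states`` is the matching ``(n, 30)`` boolean array. Gaps (missing
    seconds) are allowed but reported via :attr:`gap_seconds` so downstream
    summaries can state their coverage.
    """

    resident_id: str
    timestamps: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.states = np.asarray(self.states, dtype=bool)
        n = len(self.timestamps)
        if self.states.shape != (n, N_AREAS):
            raise StreamValidationError(
                f"states shape {self.states.shape} does not match "
                f"{n} timestamps x {N_AREAS} areas"
            )
        if n > 1:
            dt = np.diff(self.timestamps.astype("int64"))
            if np.any(dt == 0):
                raise StreamValidationError("duplicate timestamps in stream")
            if np.any(dt < 0):
                raise StreamValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameStream):
            return NotImplemented
        return (
            self.resident_id == other.resident_id
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.states, other.states)
        )

    def frame(self, i: int) -> PressureFrame:
        return PressureFrame(self.timestamps[i], self.states[i])

    def __iter__(self) -> Iterator[PressureFrame]:
        for i in range(len(self)):
            yield self.frame(i)

    @property
    def gap_seconds(self) -> int:
        """Number of missing seconds between the first and last frame."""
        if len(self) < 2:
            return 0
        span = int((self.timestamps[-1] - self.timestamps[0]).astype("int64")) + 1
        return span - len(self)


def occupancy(frame: Union[PressureFrame, Sequence[bool]]) -> bool:
    """Fallback occupancy rule for a single frame: any area pressed.

    The posture classifier provides the refined in-bed/off-bed decision; this
    rule is the model-free fallback and the definition of a non-empty frame.
    """
    states = frame.states if isinstance(frame, PressureFrame) else _as_states(frame)
    return bool(np.any(states))


def occupancy_series(stream: Union[FrameStream, np.ndarray]) -> np.ndarray:
    """Vectorised :func:`occupancy` over a stream: (n,) boolean array."""
    states = stream.states if isinstance(stream, FrameStream) else np.asarray(stream, bool)
    return np.any(states, axis=1)


_HEADER = ["timestamp"] + [f"a{i:02d}" for i in range(1, N_AREAS + 1)]


def write_frames(stream: FrameStream, path: Union[str, Path]) -> Path:
    """Write a stream to the one-row-per-second CSV dialect; returns the path."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        ts_str = np.datetime_as_string(stream.timestamps, unit="s")
        states = stream.states.astype(np.uint8)
        for t, row in zip(ts_str, states):
            w.writerow([t, *row.tolist()])
    return path


def read_frames(path: Union[str, Path], grid: SensorGrid = DEFAULT_GRID,
                resident_id: str | None = None) -> FrameStream:
    """Parse a frame CSV into a :class:`FrameStream`.

    Rows are sorted by timestamp; duplicate timestamps are rejected. Malformed
    rows raise :class:`FrameFormatError` with the offending line number.
    """
    path = Path(path)
    timestamps: list[np.datetime64] = []
    states: list[list[int]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if lineno == 1 and row[0] == "timestamp":
                continue
            if len(row) != 1 + grid.n_areas:
                raise FrameFormatError(
                    f"{path}:{lineno}: expected {1 + grid.n_areas} fields, got {len(row)}"
                )
            try:
                ts = np.datetime64(datetime.fromisoformat(row[0]), "s")
            except ValueError as exc:
                raise FrameFormatError(f"{path}:{lineno}: bad timestamp {row[0]!r}") from exc
            try:
                vals = [int(v) for v in row[1:]]
            except ValueError as exc:
                raise FrameFormatError(f"{path}:{lineno}: non-integer state field") from exc
            if any(v not in (0, 1) for v in vals):
                raise FrameFormatError(f"{path}:{lineno}: state fields must be 0 or 1")
            timestamps.append(ts)
            states.append(vals)
    ts_arr = np.array(timestamps, dtype="datetime64[s]")
    st_arr = np.array(states, dtype=bool).reshape(len(states), grid.n_areas) \
        if states else np.empty((0, grid.n_areas), bool)
    order = np.argsort(ts_arr, kind="stable")
    return FrameStream(
        resident_id=resident_id if resident_id is not None else path.stem,
        timestamps=ts_arr[order],
        states=st_arr[order],
    )
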