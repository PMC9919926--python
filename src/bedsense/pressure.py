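"""Prolonged-pressure tracking per sensing area.

Residents who stay in bed accumulate pressure on the same body sites, a
pressure-ulcer risk. Per care day and per sensing area this module reports
the longest continuous on-duration and the accumulated on-duration at 1 s
resolution, and flags areas orange when continuous pressure exceeds one hour
and red when it exceeds two (care practice repositions at-risk residents
every two hours). A single off-second breaks a run; runs spanning the 08:00
day boundary are split there, each day reporting its own portion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .frames import N_AREAS, FrameStream

ORANGE_S = 3600
RED_S = 7200

FLAG_NONE, FLAG_ORANGE, FLAG_RED = "none", "orange", "red"


@dataclass
class PressureSummary:
    """Per-area pressure durations and display flags for one day."""

    max_continuous_s: np.ndarray   # (30,) longest single run per area
    accumulated_s: np.ndarray      # (30,) total on-time per area
    flags: np.ndarray              # (30,) none / orange / red

    @property
    def worst_continuous_area(self) -> int:
        """1-based id of the area with the longest continuous pressure."""
        return int(np.argmax(self.max_continuous_s)) + 1

    @property
    def worst_accumulated_area(self) -> int:
        """1-based id of the area with the largest accumulated pressure."""
        return int(np.argmax(self.accumulated_s)) + 1

    @property
    def max_continuous_h(self) -> float:
        """Whole-mattress maximum continuous pressure time, in hours."""
        return float(self.max_continuous_s.max()) / 3600.0


def pressure_flags(max_continuous_s: np.ndarray) -> np.ndarray:
    """Display flag per area: orange above 1 h continuous, red above 2 h."""
    durations = np.asarray(max_continuous_s)
    flags = np.full(durations.shape, FLAG_NONE, dtype=object)
    flags[durations > ORANGE_S] = FLAG_ORANGE
    flags[durations > RED_S] = FLAG_RED
    return flags


def prolonged_pressure(stream: Union[FrameStream, np.ndarray]) -> PressureSummary:
    """Run-length pressure summary over one day of frames.

    Accepts a frame stream or a raw (n, 30) boolean state array; frames are
    assumed contiguous at 1 Hz (gaps count as off).
    """
    states = stream.states if isinstance(stream, FrameStream) else np.asarray(stream, bool)
    if states.ndim != 2 or states.shape[1] != N_AREAS:
        raise ValueError(f"expected an (n, {N_AREAS}) state array")
    n = len(states)
    max_cont = np.zeros(N_AREAS, dtype=np.int64)
    accum = states.sum(axis=0).astype(np.int64)
    if n:
        padded = np.zeros((n + 2, N_AREAS), dtype=bool)
        padded[1:-1] = states
        diff = padded[1:].astype(np.int8) - padded[:-1].astype(np.int8)
        for a in range(N_AREAS):
            starts = np.flatnonzero(diff[:, a] == 1)
            ends = np.flatnonzero(diff[:, a] == -1)
            if len(starts):
                max_cont[a] = int((ends - starts).max())
    return PressureSummary(
        max_continuous_s=max_cont,
        accumulated_s=accum,
        flags=pressure_flags(max_cont),
    )
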