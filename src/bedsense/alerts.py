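"""Three-stage bed-exit alerting from the posture sequence.

An exit episode runs lying -> sitting on the bed -> sitting on the edge ->
empty bed. Stage 1 fires when the resident sits up, stage 2 when they sit at
the edge, stage 3 when they leave the bed. Within one episode stages strictly
increase and each fires at most once; skipping milestones (lying straight to
empty) emits only the exit alert. Caregivers enable a subset of stages per
fall-risk level.

Raw 1 Hz classifier output can flicker; a posture change is only accepted
after it persists for the debounce window (default 3 s), so flickers shorter
than the window can never trigger an alert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Suggested stage subsets per fall-risk level (site-configurable).
RISK_PRESETS = {"high": frozenset({1, 2, 3}),
                "medium": frozenset({2, 3}),
                "low": frozenset({3})}

_STAGE_OF = {"sitting_on_bed": 1, "sitting_on_edge": 2, "empty": 3}


@dataclass(frozen=True)
class AlertEvent:
    timestamp: np.datetime64
    stage: int
    resident_id: str = ""

    def __post_init__(self) -> None:
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")


@dataclass(frozen=True)
class FallRiskConfig:
    """Which alert stages are enabled, plus smoothing/ratelimiting windows."""

    enabled_stages: frozenset = frozenset({1, 2, 3})
    refractory_s: int = 60
    debounce_s: int = 3

    def __post_init__(self) -> None:
        stages = frozenset(self.enabled_stages)
        if not stages:
            raise ValueError("at least one alert stage must be enabled")
        if not stages <= {1, 2, 3}:
            raise ValueError("stages must be a subset of {1, 2, 3}")
        object.__setattr__(self, "enabled_stages", stages)

    @staticmethod
    def for_risk(level: str) -> "FallRiskConfig":
        return FallRiskConfig(enabled_stages=RISK_PRESETS[level])


def _debounced_runs(labels: Sequence[str], debounce_s: int
                    ) -> list[tuple[int, str]]:
    """(start_second, label) of each accepted posture, after debouncing.

    A new label is accepted only once it has persisted for ``debounce_s``
    consecutive seconds; shorter flickers are ignored entirely.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if n == 0:
        return []
    changed = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], changed))
    lengths = np.diff(np.concatenate((starts, [n])))
    accepted: list[tuple[int, str]] = []
    for s, ln in zip(starts, lengths):
        lab = str(labels[s])
        if ln < debounce_s and s > 0:
            continue  # flicker shorter than the debounce window
        if not accepted or accepted[-1][1] != lab:
            accepted.append((int(s), lab))
    return accepted


def detect_bed_exit(postures: Sequence[str],
                    config: FallRiskConfig = FallRiskConfig(),
                    timestamps: Optional[np.ndarray] = None,
                    resident_id: str = "") -> list[AlertEvent]:
    """Run the bed-exit state machine over 1 Hz posture labels.

    ``timestamps`` (``datetime64[s]``, aligned with ``postures``) is optional;
    without it event timestamps are seconds-from-start. Returns the alert
    events in time order.
    """
    if timestamps is not None and len(timestamps) != len(postures):
        raise ValueError("timestamps must align with postures")

    def at(i: int) -> np.datetime64:
        if timestamps is not None:
            return np.datetime64(timestamps[i], "s")
        return np.datetime64(i, "s")

    events: list[AlertEvent] = []
    max_stage = 0          # highest milestone attained in the current episode
    episode_open = False   # an episode needs an established in-bed baseline
    refractory_until = -np.inf  # second index before which alerts are muted

    runs = _debounced_runs(postures, config.debounce_s)
    for start, label in runs:
        if label == "lying":
            episode_open = True
            max_stage = 0
            continue
        stage = _STAGE_OF.get(label)
        if stage is None:
            continue
        if not episode_open:
            # stream opened mid-posture: adopt it as baseline, do not alert
            if label != "empty":
                episode_open = True
                max_stage = stage
            continue
        if stage > max_stage:
            max_stage = stage
            if stage in config.enabled_stages and start >= refractory_until:
                events.append(AlertEvent(at(start), stage, resident_id))
        if label == "empty":
            # episode complete: resident off the bed
            episode_open = False
            max_stage = 0
            refractory_until = start + config.refractory_s
    return events
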