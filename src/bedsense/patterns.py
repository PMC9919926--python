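"""Living-pattern discovery: k-means over daily in-bed/off-bed vectors.

Each care day is one sample: its 144 binary ten-minute slots. k-means with
k = 4 recovers the four living patterns seen in long-term care — Regular
(schedule-driven nights), Free (independent, naps at will), Bedridden (in bed
around the clock) and Leave-home (bed empty for whole days). Cluster naming
is statistical: the centroid with the most mean in-bed time is Bedridden, the
least is Leave-home, and of the remaining two the one concentrating its
in-bed time in the night hours (21:00-07:00, a typical care-home lights-out
window) is Regular, the other Free — free residents get on and off the bed
during the day, diluting their night concentration.
A sustained change of a resident's daily pattern type flags a possible change
in physical condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.cluster import KMeans

from .records import N_SLOTS, DailyRecord

PATTERN_NAMES = ("Regular", "Free", "Bedridden", "Leave-home")

#: Slot indices covering 21:00 -> 07:00 on the 08:00-anchored day axis.
NIGHT_SLOTS = slice(78, 138)

#: Days a new modal type must persist before a change event is confirmed.
DEFAULT_CHANGE_WINDOW = 3


def _day_matrix(days: Sequence[Union[DailyRecord, np.ndarray]]) -> np.ndarray:
    rows = []
    for d in days:
        v = d.slots if isinstance(d, DailyRecord) else np.asarray(d)
        if v.shape != (N_SLOTS,):
            raise ValueError(f"each day must have {N_SLOTS} slots")
        rows.append(v.astype(float))
    return np.stack(rows)


def _name_centroids(centroids: np.ndarray) -> list[str]:
    """Assign the four archetype names to centroids (each exactly once)."""
    mean_in = centroids.sum(axis=1)
    order = {"Bedridden": int(np.argmax(mean_in)),
             "Leave-home": int(np.argmin(mean_in))}
    if order["Bedridden"] == order["Leave-home"]:
        raise ValueError("degenerate centroids: cannot separate archetypes")
    rest = [i for i in range(4) if i not in order.values()]
    night_frac = [
        centroids[i, NIGHT_SLOTS].sum() / max(centroids[i].sum(), 1e-9)
        for i in rest
    ]
    regular = rest[int(np.argmax(night_frac))]
    free = rest[0] if rest[1] == regular else rest[1]
    order["Regular"] = regular
    order["Free"] = free
    names = [""] * 4
    for name, idx in order.items():
        names[idx] = name
    return names


@dataclass
class LivingPatternModel:
    """Fitted k = 4 centroids over 144-dim daily vectors, with names."""

    kmeans: KMeans
    names: list[str]
    seed: int

    @property
    def centroids(self) -> np.ndarray:
        return self.kmeans.cluster_centers_

    def centroid_of(self, name: str) -> np.ndarray:
        return self.centroids[self.names.index(name)]

    def mean_in_bed_h(self, name: str) -> float:
        """Mean daily in-bed hours implied by a named centroid."""
        return max(0.0, float(self.centroid_of(name).sum())) * 10.0 / 60.0

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        joblib.dump(self, path)
        return path

    @staticmethod
    def load(path: Union[str, Path]) -> "LivingPatternModel":
        return joblib.load(path)


def fit_living_patterns(days: Sequence[Union[DailyRecord, np.ndarray]],
                        seed: int = 0) -> LivingPatternModel:
    """Cluster daily vectors into the four living patterns.

    k-means++ initialisation, 10 restarts, deterministic given the seed.
    Requires at least four distinct daily vectors.
    """
    X = _day_matrix(days)
    if len(np.unique(X, axis=0)) < 4:
        raise ValueError("fitting needs at least 4 distinct daily vectors")
    km = KMeans(n_clusters=4, init="k-means++", n_init=10, random_state=seed)
    km.fit(X)
    return LivingPatternModel(kmeans=km, names=_name_centroids(km.cluster_centers_),
                              seed=seed)


def classify_day(model: LivingPatternModel,
                 day: Union[DailyRecord, np.ndarray]) -> str:
    """Pattern name of the nearest centroid (Euclidean; ties -> lowest index)."""
    v = _day_matrix([day])[0]
    d2 = np.sum((model.centroids - v) ** 2, axis=1)
    return model.names[int(np.argmin(d2))]


@dataclass(frozen=True)
class PatternChange:
    """A confirmed switch of a resident's living-pattern type."""

    day_index: int   # 0-based index of the day confirming the change
    old: str
    new: str


def detect_pattern_change(daily_types: Sequence[str],
                          window: int = DEFAULT_CHANGE_WINDOW
                          ) -> list[PatternChange]:
    """Emit a change event when a new type persists for ``window`` days.

    The established type starts as the first day's type; a change is confirmed
    on the last day of the first run of ``window`` consecutive days that all
    carry the same different type. Blips shorter than the window never fire.
    """
    types = list(daily_types)
    if window < 1:
        raise ValueError("window must be at least 1")
    if len(types) < window:
        raise ValueError(f"need at least {window} days of types")
    events: list[PatternChange] = []
    established = types[0]
    for t in range(window - 1, len(types)):
        win = types[t - window + 1: t + 1]
        if win[0] != established and all(x == win[0] for x in win):
            events.append(PatternChange(day_index=t, old=established, new=win[0]))
            established = win[0]
    return events
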