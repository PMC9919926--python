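"""Movement counting and sleep/awake classification.

The mattress detects movement by comparing the 30-area on/off pattern of each
second with the previous second's; the count of differing seconds is
accumulated per 30 s epoch (range 0..30). A multilayer perceptron over
trailing 240 s windows (8 epochs of counts) classifies each in-bed epoch as
sleep or awake; off-bed epochs are excluded. Total sleep time divided by
total in-bed time gives the sleep efficiency percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.metrics import accuracy_score, recall_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .frames import FrameStream
from .simulate import AWAKE, EPOCH_S, OFF_BED, SLEEP, NightData

#: Number of 30 s epochs in one classification window (240 s).
WINDOW_EPOCHS = 8
_HIDDEN = (8,)
_MAX_ITER = 600

STAGE_NAMES = {SLEEP: "sleep", AWAKE: "awake", OFF_BED: "off_bed"}


def movement_counts(stream: Union[FrameStream, np.ndarray],
                    prev_frame: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-epoch movement counts for a stream of 1 Hz frames.

    A second counts as movement iff its frame differs in at least one area
    from its predecessor. The first frame of each 30 s block compares against
    the last frame of the previous block; the very first frame compares
    against ``prev_frame`` if given, otherwise it counts as no movement.
    Trailing frames that do not fill a whole epoch are ignored.
    """
    states = stream.states if isinstance(stream, FrameStream) else np.asarray(stream, bool)
    n_ep = len(states) // EPOCH_S
    states = states[: n_ep * EPOCH_S]
    if n_ep == 0:
        return np.zeros(0, dtype=np.int64)
    changed = np.empty(len(states), dtype=bool)
    changed[1:] = np.any(states[1:] != states[:-1], axis=1)
    changed[0] = bool(np.any(states[0] != prev_frame)) if prev_frame is not None else False
    return changed.reshape(n_ep, EPOCH_S).sum(axis=1)


def count_movements(frames: Union[FrameStream, np.ndarray],
                    prev_frame: Optional[np.ndarray] = None) -> int:
    """Movement count for one 30-frame epoch (see :func:`movement_counts`)."""
    states = frames.states if isinstance(frames, FrameStream) else np.asarray(frames, bool)
    if len(states) != EPOCH_S:
        raise ValueError(f"an epoch holds exactly {EPOCH_S} frames, got {len(states)}")
    return int(movement_counts(states, prev_frame)[0])


def movement_percentage(counts: Sequence[int]) -> float:
    """Percentage of time with movements per 10 min: sum of 20 consecutive
    epoch counts divided by 600 s, times 100."""
    counts = np.asarray(counts)
    if counts.shape != (20,):
        raise ValueError("movement_percentage takes exactly 20 epoch counts")
    if counts.min() < 0 or counts.max() > EPOCH_S:
        raise ValueError("epoch counts must lie in [0, 30]")
    return float(counts.sum()) / 600.0 * 100.0


@dataclass
class MovementSeries:
    """Per-epoch movement counts, optionally anchored to a start instant."""

    counts: np.ndarray
    start: Optional[np.datetime64] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) and (self.counts.min() < 0 or self.counts.max() > EPOCH_S):
            raise ValueError("movement counts must lie in [0, 30]")

    def percentages(self) -> np.ndarray:
        """Per-10-min movement percentages (20 epochs each; remainder dropped)."""
        n = len(self.counts) // 20
        blocks = self.counts[: n * 20].reshape(n, 20)
        return blocks.sum(axis=1) / 600.0 * 100.0


def build_windows(counts: np.ndarray, stages: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Trailing 8-epoch windows and the label of each window's last epoch."""
    counts = np.asarray(counts)
    stages = np.asarray(stages)
    if len(counts) != len(stages):
        raise ValueError("counts and stages must align")
    if len(counts) < WINDOW_EPOCHS:
        raise ValueError(f"need at least {WINDOW_EPOCHS} epochs")
    X = np.lib.stride_tricks.sliding_window_view(counts, WINDOW_EPOCHS).astype(float)
    return X.copy(), stages[WINDOW_EPOCHS - 1:].copy()


def windows_from_nights(nights: Sequence[NightData]) -> tuple[np.ndarray, np.ndarray]:
    """Pool training windows from several overnight recordings."""
    xs, ys = [], []
    for night in nights:
        X, y = build_windows(night.counts, night.stages)
        xs.append(X)
        ys.append(y)
    return np.concatenate(xs), np.concatenate(ys)


def _make_pipeline(seed: int) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPClassifier(hidden_layer_sizes=_HIDDEN, max_iter=_MAX_ITER,
                              early_stopping=False, random_state=seed)),
    ])


@dataclass
class SleepModel:
    """Sleep/awake classifier over 8-epoch movement-count windows."""

    pipeline: Pipeline
    seed: int
    cv_accuracy: float | None = None          # percent
    awake_sensitivity: float | None = None    # percent

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Stage code (SLEEP/AWAKE) per window."""
        return self.pipeline.predict(np.asarray(windows, dtype=float))

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        joblib.dump(self, path)
        return path

    @staticmethod
    def load(path: Union[str, Path]) -> "SleepModel":
        return joblib.load(path)


def train_sleep_model(X: np.ndarray, y: np.ndarray, n_folds: int = 10,
                      seed: int = 0) -> tuple[SleepModel, float, float]:
    """Train the sleep/awake model with stratified cross-validation.

    ``y`` holds stage codes (SLEEP=0, AWAKE=1). Returns the refit model, the
    CV accuracy in percent, and the cross-validated sensitivity (recall) of
    the awake class in percent — awake epochs are the minority during a night
    in bed, so their recall is reported separately.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != WINDOW_EPOCHS:
        raise ValueError(f"windows must have exactly {WINDOW_EPOCHS} epochs")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both sleep and awake epochs")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(_make_pipeline(seed), X, y, cv=cv)
    acc = float(accuracy_score(y, pred)) * 100.0
    sens = float(recall_score(y, pred, pos_label=AWAKE)) * 100.0
    final = _make_pipeline(seed).fit(X, y)
    model = SleepModel(pipeline=final, seed=seed,
                       cv_accuracy=acc, awake_sensitivity=sens)
    return model, acc, sens


def fit_sleep_model(X: np.ndarray, y: np.ndarray, seed: int = 0) -> SleepModel:
    """Fit on all data without cross-validation (pipeline fast path)."""
    pipe = _make_pipeline(seed).fit(np.asarray(X, dtype=float), np.asarray(y))
    return SleepModel(pipeline=pipe, seed=seed)


@dataclass
class SleepRecord:
    """Per-epoch sleep staging for one care day plus its summary numbers.

    Invariant: sleep + awake epochs partition the in-bed epochs exactly, so
    total sleep time plus total awake time equals total in-bed time.
    """

    epoch_states: np.ndarray          # (n,) SLEEP / AWAKE / OFF_BED
    total_sleep_s: int
    total_in_bed_s: int
    sleep_efficiency: Optional[float]  # percent; None when never in bed

    @property
    def total_awake_s(self) -> int:
        return self.total_in_bed_s - self.total_sleep_s


def classify_sleep(model: SleepModel, counts: np.ndarray,
                   epoch_occupancy: np.ndarray) -> SleepRecord:
    """Stage every epoch of a day and compute the sleep summary.

    ``epoch_occupancy`` marks in-bed epochs (majority occupancy within the
    epoch). Each in-bed epoch is labelled from its trailing 8-epoch window
    within the same in-bed bout; the first 7 epochs of a bout reuse the first
    full window's label, and bouts shorter than 8 epochs are left-padded with
    their first count. Sleep efficiency = total sleep / total in-bed x 100.
    """
    counts = np.asarray(counts)
    occ = np.asarray(epoch_occupancy, dtype=bool)
    if counts.shape != occ.shape:
        raise ValueError("counts and occupancy must align")
    n = len(counts)
    states = np.full(n, OFF_BED, dtype=np.int8)

    # walk in-bed bouts (runs of consecutive occupied epochs)
    i = 0
    while i < n:
        if not occ[i]:
            i += 1
            continue
        j = i
        while j < n and occ[j]:
            j += 1
        bout = counts[i:j]
        m = len(bout)
        if m >= WINDOW_EPOCHS:
            X = np.lib.stride_tricks.sliding_window_view(bout, WINDOW_EPOCHS).astype(float)
            pred = model.predict(X)
            states[i + WINDOW_EPOCHS - 1: j] = pred
            states[i: i + WINDOW_EPOCHS - 1] = pred[0]
        else:
            padded = np.concatenate([np.full(WINDOW_EPOCHS - m, bout[0]), bout])
            states[i:j] = model.predict(padded[None, :])[0]
        i = j

    n_in = int(occ.sum())
    n_sleep = int(np.sum(states == SLEEP))
    total_in = n_in * EPOCH_S
    total_sleep = n_sleep * EPOCH_S
    eff = (total_sleep / total_in * 100.0) if total_in > 0 else None
    return SleepRecord(
        epoch_states=states,
        total_sleep_s=total_sleep,
        total_in_bed_s=total_in,
        sleep_efficiency=eff,
    )


def sleep_efficiency(total_sleep_s: float, total_in_bed_s: float) -> Optional[float]:
    """Sleep efficiency in percent; None for zero in-bed time."""
    if total_in_bed_s <= 0:
        return None
    return total_sleep_s / total_in_bed_s * 100.0
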