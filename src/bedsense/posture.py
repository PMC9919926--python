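"""In-bed posture identification from a single frame's 30 on/off states.

A small multilayer perceptron maps the 30 binary features to one of four
classes: lying, sitting on the bed, sitting on the edge of the bed, or empty
bed. An all-off frame is definitionally an empty bed and is forced to the
``empty`` class regardless of the learned decision function.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, classification_report
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier

from .frames import N_AREAS, FrameStream, PressureFrame
from .simulate import POSTURES, PostureDataset

_HIDDEN = (16,)
_MAX_ITER = 600


def extract_features(frame: Union[PressureFrame, Sequence[bool]]) -> np.ndarray:
    """The 30-element binary feature vector, ordered by grid area id.

    The mapping is a bijection: the feature vector reconstructs the frame's
    states exactly.
    """
    states = frame.states if isinstance(frame, PressureFrame) else np.asarray(frame)
    states = states.astype(bool)
    if states.shape != (N_AREAS,):
        raise ValueError(f"expected {N_AREAS} states, got shape {states.shape}")
    return states.astype(np.float64)


def _make_mlp(seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=_HIDDEN,
        max_iter=_MAX_ITER,
        early_stopping=False,
        random_state=seed,
    )


@dataclass
class PostureModel:
    """A trained posture classifier plus its training metadata."""

    classifier: MLPClassifier
    seed: int
    cv_accuracy: float | None = None       # percent
    class_metrics: pd.DataFrame | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predict posture labels for an (n, 30) feature matrix.

        All-off rows return ``empty`` unconditionally (hard rule).
        """
        features = np.asarray(features, dtype=np.float64)
        if features.ndim == 1:
            features = features[None, :]
        out = self.classifier.predict(features).astype(object)
        out[~features.any(axis=1)] = "empty"
        return out.astype(str)

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        joblib.dump(self, path)
        return path

    @staticmethod
    def load(path: Union[str, Path]) -> "PostureModel":
        return joblib.load(path)


def train_posture_model(dataset: Union[PostureDataset, tuple],
                        n_folds: int = 10, seed: int = 0,
                        ) -> tuple[PostureModel, float, pd.DataFrame]:
    """Train the posture model with stratified cross-validation.

    Returns the final model (refit on all data), the CV accuracy in percent,
    and a per-class precision/recall table. Deterministic given the seed:
    fold assignment and network initialisation both derive from it.
    """
    if isinstance(dataset, PostureDataset):
        X, y = dataset.features, dataset.labels
    else:
        X, y = dataset
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    present = set(np.unique(y))
    missing = [c for c in POSTURES if c not in present]
    if missing:
        raise ValueError(f"training data is missing class(es): {', '.join(missing)}")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError(f"need at least 2 examples per class; got {counts.to_dict()}")

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(_make_mlp(seed), X, y, cv=cv)
    acc = float(accuracy_score(y, pred)) * 100.0
    report = pd.DataFrame(
        classification_report(y, pred, output_dict=True, zero_division=0)
    ).T

    final = _make_mlp(seed).fit(X, y)
    model = PostureModel(classifier=final, seed=seed,
                         cv_accuracy=acc, class_metrics=report)
    return model, acc, report


def fit_posture_model(dataset: Union[PostureDataset, tuple],
                      seed: int = 0) -> PostureModel:
    """Fit on all data without cross-validation (pipeline fast path)."""
    if isinstance(dataset, PostureDataset):
        X, y = dataset.features, dataset.labels
    else:
        X, y = dataset
    clf = _make_mlp(seed).fit(np.asarray(X, dtype=np.float64), np.asarray(y))
    return PostureModel(classifier=clf, seed=seed)


def classify_posture(model: PostureModel,
                     frame: Union[PressureFrame, Sequence[bool]]) -> str:
    """Posture label for one frame (hard empty rule applies)."""
    return str(model.predict(extract_features(frame)[None, :])[0])


def classify_stream(model: PostureModel,
                    stream: Union[FrameStream, np.ndarray]) -> np.ndarray:
    """Posture label per frame of a stream.

    Consecutive identical frames are classified once and the label repeated,
    which keeps full-day (86 400 frame) classification cheap; output length
    always equals the frame count.
    """
    states = stream.states if isinstance(stream, FrameStream) else np.asarray(stream, bool)
    n = len(states)
    if n == 0:
        return np.empty(0, dtype=object)
    changed = np.any(states[1:] != states[:-1], axis=1)
    starts = np.concatenate(([0], np.flatnonzero(changed) + 1))
    reps = np.diff(np.concatenate((starts, [n])))
    labels = model.predict(states[starts].astype(np.float64))
    return np.repeat(labels, reps)
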