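"""Shared fixtures. Heavy model experiments are session-scoped so unit and
acceptance tests reuse one computation."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import bedsense as bs

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def posture_dataset():
    """The default collection design: 31 participants x 30 + 80 empty."""
    return bs.generate_posture_dataset(31, 30, 80, seed=0)


@pytest.fixture(scope="session")
def posture_cv(posture_dataset):
    """(model, cv_accuracy_pct, per_class_report) with 10-fold CV."""
    return bs.train_posture_model(posture_dataset, n_folds=10, seed=0)


@pytest.fixture(scope="session")
def sleep_nights():
    """Five simulated ~8 h overnight recordings with default movement rates."""
    return [bs.simulate_night(8.0, seed=1000 + i) for i in range(5)]


@pytest.fixture(scope="session")
def sleep_cv(sleep_nights):
    """(model, cv_accuracy_pct, awake_sensitivity_pct) on pooled windows."""
    X, y = bs.windows_from_nights(sleep_nights)
    return bs.train_sleep_model(X, y, n_folds=10, seed=0)


@pytest.fixture(scope="session")
def noiseless_templates():
    return bs.default_templates(jitter_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_posture_model(noiseless_templates):
    """Model trained on perfectly separable template data (tiny, fast)."""
    ds = bs.generate_posture_dataset(6, 6, 8, seed=3,
                                     templates=noiseless_templates)
    model, acc, _ = bs.train_posture_model(ds, n_folds=2, seed=0)
    return model, acc, ds
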