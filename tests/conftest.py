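"""Shared fixtures: small cameras and cached heavy simulation results.

Ensemble-level results are computed once per session and shared between
tests; unit tests use miniature grids so the whole suite stays fast.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pytest

from headingflow.experiments import (
    ExperimentSpec,
    run_experiment,
    run_trial,
)
from headingflow.stimulus import CameraModel

warnings.filterwarnings("ignore", message="no opponent motion response")

#: reduced ensemble size used by the test suite; the acceptance script runs
#: the full 25-trial protocol
N_TRIALS_TEST = 8


@pytest.fixture(scope="session")
def small_camera() -> CameraModel:
    """A tiny symmetric camera for fast unit tests."""
    return CameraModel(width=33, height=25, fov_deg=100.0)


@lru_cache(maxsize=None)
def cached_trial(condition: str, model: str = "competitive", seed: int = 0, **kw):
    return run_trial(condition, model=model, seed=seed, **kw)


@lru_cache(maxsize=None)
def cached_ensemble(condition: str, model: str = "competitive", n_frames: int = 45):
    spec = ExperimentSpec(
        condition=condition,
        model=model,
        n_trials=N_TRIALS_TEST,
        base_seed=0,
        n_frames=n_frames,
    )
    summary, traces = run_experiment(spec)
    return summary, traces


@pytest.fixture(scope="session")
def trial():
    """Session-cached single-trial runner."""
    return cached_trial


@pytest.fixture(scope="session")
def ensemble():
    """Session-cached reduced-ensemble runner."""
    return cached_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
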