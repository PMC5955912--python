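"""Shared fixtures: small simulated cohorts and an analytic dome model."""

from __future__ import annotations

import numpy as np
import pytest

from olrkit.design import ExperimentDesign, make_conditions
from olrkit.synth import CohortSpec, TuningModel, simulate_cohort


def small_design(experiment: str = "speed", repeats: int = 3, sessions: int = 2) -> ExperimentDesign:
    return ExperimentDesign(
        experiment, tuple(make_conditions(experiment)), repeats_per_session=repeats, n_sessions=sessions
    )


@pytest.fixture(scope="session")
def tuning():
    return TuningModel(peak_speed=57.2, peak_olr=35.0)


@pytest.fixture(scope="session")
def small_cohort(tuning):
    """3 mice, 36 speed conditions, 3 repeats x 2 sessions, moderate noise."""
    spec = CohortSpec(noise_sd=8.0, baseline_drift_sd=2.0)
    dataset, truth = simulate_cohort(small_design(), 3, spec, rng=101, tuning=tuning)
    return dataset, truth


@pytest.fixture(scope="session")
def quiet_cohort(tuning):
    """3 mice, noise-free except per-trial drift; for exact-recovery checks."""
    spec = CohortSpec(
        noise_sd=0.0,
        baseline_drift_sd=2.0,
        latency_jitter_sd=0.0,
        time_constant_jitter_sd=0.0,
    )
    dataset, truth = simulate_cohort(
        small_design(repeats=1, sessions=1), 3, spec, rng=7, tuning=tuning
    )
    return dataset, truth


# -- analytic dome model for LUT tests --------------------------------------

PROJ_W, PROJ_H = 1920.0, 1080.0


def dome_forward(x, y):
    """Smooth synthetic projector->dome mapping (degrees), monotone per axis."""
    u = np.asarray(x, dtype=float) / PROJ_W
    v = np.asarray(y, dtype=float) / PROJ_H
    azi = -110.0 + 220.0 * u + 6.0 * np.sin(np.pi * v) * (u - 0.5)
    ele = -10.0 + 90.0 * v + 4.0 * np.sin(np.pi * u) * v * (1.0 - v)
    return azi, ele


def dome_grid(n_cols: int = 20, n_rows: int = 10):
    """Node measurements of the synthetic dome on an evenly spaced pixel raster."""
    xs = np.linspace(0.0, PROJ_W, n_cols)
    ys = np.linspace(0.0, PROJ_H, n_rows)
    X, Y = np.meshgrid(xs, ys)
    A, E = dome_forward(X, Y)
    return {"x": X.ravel(), "y": Y.ravel(), "azi": A.ravel(), "ele": E.ravel()}
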