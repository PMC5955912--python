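"""Seeded miniature datasets for tests, docs and pipeline smoke runs.

All fixtures are *synthetic*: small cohorts generated by the response
model in :mod:`olrkit.synth`, written as plain CSV with the ground truth
recorded in a JSON sidecar.  The same seed always yields byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .design import ExperimentDesign, make_conditions
from .exceptions import ArgumentError
from .synth import CohortSpec, default_tuning, simulate_cohort

__all__ = ["generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("tiny_speed", "tiny_surface")


def generate_fixture(kind: str, seed: int, directory) -> Path:
    """Write a deterministic miniature cohort dataset.

    ``tiny_speed``: 3 mice, all 36 speed-experiment conditions, 3 repeats
    over 1 session.  ``tiny_surface``: 3 mice, all 100 contrast-experiment
    conditions, 2 repeats over 1 session.  Produces ``trials.csv``,
    ``samples.csv`` and ``truth.json`` under ``directory``.
    """
    if kind not in FIXTURE_KINDS:
        raise ArgumentError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    if kind == "tiny_speed":
        design = ExperimentDesign(
            "speed", tuple(make_conditions("speed")), repeats_per_session=3, n_sessions=1
        )
    else:
        design = ExperimentDesign(
            "contrast", tuple(make_conditions("contrast")), repeats_per_session=2, n_sessions=1
        )
    spec = CohortSpec(noise_sd=5.0, baseline_drift_sd=1.0)
    dataset, truth = simulate_cohort(
        design, n_mice=3, cohort_spec=spec, rng=np.random.default_rng(seed), tuning=default_tuning()
    )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.write_csv(directory)
    truth["seed"] = seed
    truth["kind"] = kind
    (directory / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return directory
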