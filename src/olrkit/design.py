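"""Experiment design: condition grids, randomized session schedules, trial timelines.

Three experiments are supported:

``speed``
    9 speeds (0–72 deg/s in steps of 9) x 2 directions x 2 motion-onset
    times = 36 conditions; 10 repeats per session, 7 sessions.
``contrast``
    5 speeds (0, 18, 36, 54, 72 deg/s) x 2 directions x 2 onsets x
    5 Michelson contrasts = 100 conditions; 5 repeats per session,
    14 sessions.
``dotsize``
    as ``contrast`` but varying dot radius instead (5 radii).

Each plan gives 70 presentations per condition in total.  The zero-speed
condition is part of every grid: its response curve is subtracted from
all motion conditions during preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ArgumentError

__all__ = [
    "SPEEDS_SPEED_EXP",
    "SPEEDS_SURFACE_EXP",
    "CONTRAST_LABELS",
    "DOT_LUMINANCES",
    "BACKGROUND_LUMINANCE",
    "DOT_RADII",
    "DEFAULT_CONTRAST",
    "DEFAULT_DOT_RADIUS",
    "STATIC_PRE_CHOICES",
    "TrialCondition",
    "TrialTimeline",
    "SessionSchedule",
    "ExperimentDesign",
    "michelson_contrast",
    "contrast_table",
    "make_conditions",
    "make_schedule",
    "make_design",
    "total_repeats",
    "schedule_to_frame",
    "write_schedule_csv",
    "read_schedule_csv",
]

SPEEDS_SPEED_EXP: tuple[float, ...] = tuple(float(s) for s in range(0, 73, 9))
SPEEDS_SURFACE_EXP: tuple[float, ...] = (0.0, 18.0, 36.0, 54.0, 72.0)
#: printed contrast labels; attached as metadata (see `contrast_table`)
CONTRAST_LABELS: tuple[float, ...] = (0.09, 0.37, 0.68, 0.89, 0.95)
DOT_LUMINANCES: tuple[float, ...] = (0.11, 0.20, 0.5, 1.66, 3.98)  # cd/m^2
BACKGROUND_LUMINANCE: float = 0.09  # cd/m^2
DOT_RADII: tuple[float, ...] = (0.6, 0.9, 1.4, 2.3, 3.7)  # degrees
DEFAULT_CONTRAST: float = 0.68
DEFAULT_DOT_RADIUS: float = 1.4
STATIC_PRE_CHOICES: tuple[int, ...] = (1, 2)  # s of static dots before motion
DIRECTIONS: tuple[str, str] = ("left", "right")


@dataclass(frozen=True)
class TrialCondition:
    """One stimulus condition.

    ``static_pre`` is the duration (s) of the static dot phase before
    motion onset; randomly interleaving 1 and 2 s reduces anticipation of
    the onset.  The zero-speed condition keeps both direction labels as
    distinct conditions, which reproduces the printed condition counts.
    """

    speed: float  # deg/s
    direction: str  # 'left' | 'right'
    static_pre: int  # s, 1 or 2
    contrast: float = DEFAULT_CONTRAST  # Michelson label
    dot_radius: float = DEFAULT_DOT_RADIUS  # degrees

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ArgumentError("speed must be >= 0")
        if self.direction not in DIRECTIONS:
            raise ArgumentError(f"direction must be one of {DIRECTIONS}")
        if self.static_pre not in STATIC_PRE_CHOICES:
            raise ArgumentError("static_pre must be 1 or 2 s")
        if not 0 < self.contrast <= 1:
            raise ArgumentError("contrast must be in (0, 1]")
        if self.dot_radius <= 0:
            raise ArgumentError("dot_radius must be positive")

    @property
    def timeline(self) -> "TrialTimeline":
        return TrialTimeline(static_pre=float(self.static_pre))


@dataclass(frozen=True)
class TrialTimeline:
    """Stimulus time course of one trial: static, 2 s motion, 1 s static."""

    static_pre: float  # s, 1 or 2
    motion: float = 2.0
    static_post: float = 1.0

    def __post_init__(self) -> None:
        if self.static_pre not in (1.0, 2.0):
            raise ArgumentError("static_pre must be 1 or 2 s")

    @property
    def duration(self) -> float:
        return self.static_pre + self.motion + self.static_post

    @property
    def motion_onset(self) -> float:
        """Time of motion onset (t = 0 of the analysis) from trial start."""
        return self.static_pre

    def n_samples(self, fs: float = 60.0) -> int:
        return int(round(self.duration * fs))

    def t0_index(self, fs: float = 60.0) -> int:
        return int(round(self.static_pre * fs))


@dataclass(frozen=True)
class SessionSchedule:
    """Randomized interleaved trial order for one session."""

    trials: tuple[TrialCondition, ...]
    repeats_per_session: int
    session_id: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def block(self, k: int) -> tuple[TrialCondition, ...]:
        n = self.n_trials // self.repeats_per_session
        return self.trials[k * n : (k + 1) * n]


@dataclass(frozen=True)
class ExperimentDesign:
    """Condition grid plus the session plan of one experiment."""

    name: str
    conditions: tuple[TrialCondition, ...]
    repeats_per_session: int
    n_sessions: int

    @property
    def total_repeats(self) -> int:
        return total_repeats(self.repeats_per_session, self.n_sessions)

    @property
    def varied_factor(self) -> str | None:
        """Secondary factor varied besides speed ('contrast', 'dot_radius' or None)."""
        if len({c.contrast for c in self.conditions}) > 1:
            return "contrast"
        if len({c.dot_radius for c in self.conditions}) > 1:
            return "dot_radius"
        return None


def michelson_contrast(dot_luminance: float, background_luminance: float) -> float:
    """Michelson contrast ``(Lmax - Lmin) / (Lmax + Lmin)`` of dot vs background."""
    if dot_luminance <= 0 or background_luminance <= 0:
        raise ArgumentError("luminances must be positive")
    lo, hi = sorted((dot_luminance, background_luminance))
    return (hi - lo) / (hi + lo)


def contrast_table() -> pd.DataFrame:
    """Printed contrast labels next to contrasts recomputed from the luminances.

    The labels are attached to conditions as metadata rather than
    recomputed at run time: recomputing from the luminances as printed
    (rounded to 2–3 digits) does not reproduce the labels in the second
    decimal, so the labels are treated as authoritative condition names.
    """
    computed = [michelson_contrast(l, BACKGROUND_LUMINANCE) for l in DOT_LUMINANCES]
    return pd.DataFrame(
        {
            "dot_luminance_cd_m2": DOT_LUMINANCES,
            "background_cd_m2": BACKGROUND_LUMINANCE,
            "contrast_label": CONTRAST_LABELS,
            "contrast_computed": computed,
        }
    )


_EXPERIMENTS = ("speed", "contrast", "dotsize")


def make_conditions(experiment: str) -> list[TrialCondition]:
    """Full factorial condition list for one experiment.

    ``speed``: 9 speeds x 2 directions x 2 onsets = 36.
    ``contrast``/``dotsize``: 5 speeds x 2 directions x 2 onsets x
    5 contrast or radius levels = 100.
    """
    if experiment not in _EXPERIMENTS:
        raise ArgumentError(f"unknown experiment {experiment!r}; expected one of {_EXPERIMENTS}")
    if experiment == "speed":
        speeds: Sequence[float] = SPEEDS_SPEED_EXP
        contrasts: Sequence[float] = (DEFAULT_CONTRAST,)
        radii: Sequence[float] = (DEFAULT_DOT_RADIUS,)
    elif experiment == "contrast":
        speeds = SPEEDS_SURFACE_EXP
        contrasts = CONTRAST_LABELS
        radii = (DEFAULT_DOT_RADIUS,)
    else:  # dotsize
        speeds = SPEEDS_SURFACE_EXP
        contrasts = (DEFAULT_CONTRAST,)
        radii = DOT_RADII
    return [
        TrialCondition(speed=s, direction=d, static_pre=p, contrast=c, dot_radius=r)
        for c in contrasts
        for r in radii
        for s in speeds
        for d in DIRECTIONS
        for p in STATIC_PRE_CHOICES
    ]


def make_schedule(
    conditions: Sequence[TrialCondition],
    repeats_per_session: int,
    rng: np.random.Generator | int | None = None,
    session_id: int = 0,
) -> SessionSchedule:
    """Randomly interleaved block design: per repeat, a fresh permutation of all conditions."""
    if len(conditions) == 0:
        raise ArgumentError("conditions must be non-empty")
    if repeats_per_session < 1:
        raise ArgumentError("repeats_per_session must be >= 1")
    gen = np.random.default_rng(rng)
    trials: list[TrialCondition] = []
    for _ in range(repeats_per_session):
        order = gen.permutation(len(conditions))
        trials.extend(conditions[i] for i in order)
    return SessionSchedule(tuple(trials), repeats_per_session, session_id)


def make_design(experiment: str) -> ExperimentDesign:
    """Condition grid and session plan (repeats, sessions) of one experiment."""
    conditions = tuple(make_conditions(experiment))
    if experiment == "speed":
        return ExperimentDesign("speed", conditions, repeats_per_session=10, n_sessions=7)
    return ExperimentDesign(experiment, conditions, repeats_per_session=5, n_sessions=14)


def total_repeats(repeats_per_session: int, n_sessions: int) -> int:
    """Total presentations of each condition over the whole experiment."""
    if repeats_per_session < 0 or n_sessions < 0:
        raise ArgumentError("counts must be >= 0")
    return repeats_per_session * n_sessions


def schedule_to_frame(schedule: SessionSchedule) -> pd.DataFrame:
    n_cond = schedule.n_trials // schedule.repeats_per_session
    return pd.DataFrame(
        {
            "trial": np.arange(schedule.n_trials),
            "block": np.arange(schedule.n_trials) // n_cond,
            "speed_deg_s": [c.speed for c in schedule.trials],
            "direction": [c.direction for c in schedule.trials],
            "static_pre_s": [c.static_pre for c in schedule.trials],
            "contrast": [c.contrast for c in schedule.trials],
            "dot_radius_deg": [c.dot_radius for c in schedule.trials],
        }
    )


def write_schedule_csv(schedule: SessionSchedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def read_schedule_csv(path) -> SessionSchedule:
    df = pd.read_csv(path)
    trials = tuple(
        TrialCondition(
            speed=row.speed_deg_s,
            direction=row.direction,
            static_pre=int(row.static_pre_s),
            contrast=row.contrast,
            dot_radius=row.dot_radius_deg,
        )
        for row in df.itertuples()
    )
    n_blocks = int(df["block"].max()) + 1
    return SessionSchedule(trials, repeats_per_session=n_blocks)
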