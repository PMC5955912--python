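"""Synthetic yaw-trace cohorts with known ground-truth tuning.

Generates per-trial 60 Hz ball-yaw time series for a simulated cohort of
head-fixed mice running on a spherical treadmill while a whole-field dot
pattern drifts in yaw.  Every downstream analysis stage (smoothing,
baseline subtraction, folding, normalization, tuning fits, bootstrap peak
estimation) can then be exercised against a known truth.

Response model (per trial)
--------------------------
``yaw(t) = drift + g_m * f(cond) * sign(dir) * h(t) + noise(t)``

* ``f(cond)`` — deterministic tuning surface (plateau yaw in deg/s):
  concave quadratic in speed (zero at speed 0, maximum at the true peak)
  times saturating factors in contrast and dot size, each equal to 1 at
  the reference contrast 0.68 and radius 1.4 deg.
* ``g_m`` — per-mouse gain multiplier; log-spread across the cohort with
  a max/min ratio of ``gain_spread`` (default 3, emulating the near
  threefold amplitude spread between the weakest and strongest
  responder), rescaled to arithmetic mean 1 so the cohort mean equals
  ``f``.
* ``h(t)`` — first-order (exponential) step response: zero until motion
  onset plus a latency, rising with time constant ``tau`` during the 2 s
  motion, decaying after motion offset (plus the same latency).
* ``drift`` — per-trial constant baseline offset (forward-running bias),
  removed exactly by the 500 ms baseline subtraction.
* ``noise`` — white Gaussian at the 60 Hz sample level.

Sign convention: positive yaw means the mouse turns *with* the stimulus
(the analysis-facing sign; a raw rig export in ball coordinates would be
negated once at ingest).

The trial-to-trial variability and latency of the real preparation are
not characterized in the assay literature; the defaults here are
stand-ins chosen to look like the published mean response traces (smooth
rise to plateau well within 1 s) while leaving the 1–2 s measurement
window essentially at plateau.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ExperimentDesign, TrialCondition, TrialTimeline, make_schedule
from .exceptions import ArgumentError, DataError

__all__ = [
    "MouseParams",
    "CohortSpec",
    "TuningModel",
    "YawTrace",
    "TrialDataset",
    "default_tuning",
    "step_response",
    "simulate_trial",
    "draw_cohort",
    "simulate_cohort",
]

FS: float = 60.0  # Hz sample rate of the ball readout


@dataclass(frozen=True)
class MouseParams:
    """Response parameters of one simulated mouse."""

    gain_multiplier: float = 1.0  # scales the tuning surface
    latency: float = 0.10  # s from motion onset to response onset
    time_constant: float = 0.12  # s, first-order rise/decay
    noise_sd: float = 15.0  # deg/s white noise per 60 Hz sample
    baseline_drift_sd: float = 3.0  # deg/s SD of per-trial constant offset

    def __post_init__(self) -> None:
        if self.gain_multiplier <= 0:
            raise ArgumentError("gain_multiplier must be > 0")
        if self.latency < 0 or self.time_constant <= 0:
            raise ArgumentError("latency must be >= 0 and time_constant > 0")
        if self.noise_sd < 0 or self.baseline_drift_sd < 0:
            raise ArgumentError("noise parameters must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Population-level settings for :func:`draw_cohort`."""

    gain_spread: float = 3.0  # max/min ratio of gain multipliers
    latency: float = 0.10
    latency_jitter_sd: float = 0.02
    time_constant: float = 0.12
    time_constant_jitter_sd: float = 0.02
    noise_sd: float = 15.0
    baseline_drift_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.gain_spread < 1:
            raise ArgumentError("gain_spread must be >= 1")


class TuningModel:
    """Ground-truth tuning surface ``f(speed, contrast, dot_radius)`` in deg/s.

    Speed tuning is the concave quadratic
    ``f_s(s) = peak_olr * (1 - ((s - peak_speed)/peak_speed)**2)``,
    which is zero at speed 0 and maximal (``peak_olr``) at ``peak_speed``.
    Contrast and dot size act as multiplicative saturating factors
    ``(x/(x+x50)) / (x_ref/(x_ref+x50))`` that equal 1 at the reference
    levels, so in single-factor experiments the surface reduces to the
    speed tuning alone.
    """

    def __init__(
        self,
        peak_speed: float = 57.2,
        peak_olr: float = 35.0,
        contrast_halfsat: float = 0.30,
        size_halfsat: float = 0.80,
        ref_contrast: float = 0.68,
        ref_dot_radius: float = 1.4,
    ):
        if peak_speed <= 0:
            raise ArgumentError("peak_speed must be positive")
        self.peak_speed = float(peak_speed)
        self.peak_olr = float(peak_olr)
        self.contrast_halfsat = float(contrast_halfsat)
        self.size_halfsat = float(size_halfsat)
        self.ref_contrast = float(ref_contrast)
        self.ref_dot_radius = float(ref_dot_radius)

    def __call__(self, speed, contrast=None, dot_radius=None):
        s = np.asarray(speed, dtype=float)
        out = self.peak_olr * (1.0 - ((s - self.peak_speed) / self.peak_speed) ** 2)
        if contrast is not None:
            c = np.asarray(contrast, dtype=float)
            out = out * (c / (c + self.contrast_halfsat)) / (
                self.ref_contrast / (self.ref_contrast + self.contrast_halfsat)
            )
        if dot_radius is not None:
            r = np.asarray(dot_radius, dtype=float)
            out = out * (r / (r + self.size_halfsat)) / (
                self.ref_dot_radius / (self.ref_dot_radius + self.size_halfsat)
            )
        return out if out.ndim else float(out)

    def plateau(self, condition: TrialCondition) -> float:
        return float(self(condition.speed, condition.contrast, condition.dot_radius))

    def to_dict(self) -> dict:
        return {
            "peak_speed": self.peak_speed,
            "peak_olr": self.peak_olr,
            "contrast_halfsat": self.contrast_halfsat,
            "size_halfsat": self.size_halfsat,
            "ref_contrast": self.ref_contrast,
            "ref_dot_radius": self.ref_dot_radius,
        }


def default_tuning(peak_speed: float = 57.2, peak_olr: float = 35.0) -> TuningModel:
    """Tuning model peaking at ``(peak_speed, peak_olr)`` and zero at speed 0."""
    return TuningModel(peak_speed=peak_speed, peak_olr=peak_olr)


@dataclass
class YawTrace:
    """One trial's ball-yaw time series (deg/s at 60 Hz) plus metadata."""

    samples: np.ndarray
    t0_index: int  # sample index of motion onset
    condition: TrialCondition | None = None
    mouse_id: int = 0
    session_id: int = 0
    trial_id: int = 0
    fs: float = FS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ArgumentError("samples must be 1-D")
        if not 0 <= self.t0_index <= self.samples.size:
            raise ArgumentError("t0_index outside the trace")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def time(self) -> np.ndarray:
        """Sample times in s relative to motion onset."""
        return (np.arange(self.n_samples) - self.t0_index) / self.fs


def step_response(
    n_samples: int,
    t0_index: int,
    latency: float,
    time_constant: float,
    motion_s: float = 2.0,
    fs: float = FS,
) -> np.ndarray:
    """Unit first-order step response sampled at ``fs``.

    Input is 1 during ``[t0 + latency, t0 + motion_s + latency)`` and 0
    elsewhere (the latency delays both onset and offset); the output is
    the exact zero-order-hold solution of ``tau * dr/dt = u - r``.
    """
    dt = 1.0 / fs
    t = np.arange(n_samples) * dt
    t0 = t0_index * dt
    u = ((t >= t0 + latency) & (t < t0 + motion_s + latency)).astype(float)
    a = 1.0 - np.exp(-dt / time_constant)
    r = np.empty(n_samples)
    acc = 0.0
    for k in range(n_samples):
        acc += (u[k] - acc) * a
        r[k] = acc
    return r


def simulate_trial(
    condition: TrialCondition,
    mouse: MouseParams,
    tuning: TuningModel,
    timeline: TrialTimeline | None = None,
    rng: np.random.Generator | int | None = None,
    mouse_id: int = 0,
    session_id: int = 0,
    trial_id: int = 0,
) -> YawTrace:
    """Simulate one trial's yaw trace under the response model."""
    if timeline is None:
        timeline = condition.timeline
    gen = np.random.default_rng(rng)
    n = timeline.n_samples(FS)
    t0 = timeline.t0_index(FS)
    sign = 1.0 if condition.direction == "right" else -1.0
    plateau = mouse.gain_multiplier * tuning.plateau(condition)
    yaw = plateau * sign * step_response(n, t0, mouse.latency, mouse.time_constant, timeline.motion, FS)
    if mouse.baseline_drift_sd > 0:
        yaw = yaw + gen.normal(0.0, mouse.baseline_drift_sd)
    if mouse.noise_sd > 0:
        yaw = yaw + gen.normal(0.0, mouse.noise_sd, size=n)
    return YawTrace(yaw, t0, condition, mouse_id, session_id, trial_id)


def draw_cohort(
    n_mice: int,
    spec: CohortSpec = CohortSpec(),
    rng: np.random.Generator | int | None = None,
) -> list[MouseParams]:
    """Per-mouse parameters for a cohort.

    Gain multipliers are log-spaced between ``1/sqrt(spread)`` and
    ``sqrt(spread)`` (max/min ratio exactly ``gain_spread``) and rescaled
    to arithmetic mean 1; latency and time constant get small Gaussian
    jitter around the cohort values.
    """
    if n_mice < 1:
        raise ArgumentError("n_mice must be >= 1")
    gen = np.random.default_rng(rng)
    if n_mice == 1 or spec.gain_spread == 1.0:
        gains = np.ones(n_mice)
    else:
        half = np.sqrt(spec.gain_spread)
        gains = np.geomspace(1.0 / half, half, n_mice)
        gains = gains / gains.mean()
    mice = []
    for g in gains:
        lat = max(0.0, gen.normal(spec.latency, spec.latency_jitter_sd))
        tau = max(0.05, gen.normal(spec.time_constant, spec.time_constant_jitter_sd))
        mice.append(
            MouseParams(
                gain_multiplier=float(g),
                latency=float(lat),
                time_constant=float(tau),
                noise_sd=spec.noise_sd,
                baseline_drift_sd=spec.baseline_drift_sd,
            )
        )
    return mice


_META_COLUMNS = [
    "mouse",
    "session",
    "trial",
    "block",
    "speed",
    "direction",
    "static_pre",
    "contrast",
    "dot_radius",
    "group",
    "row",
]


class TrialDataset:
    """Cohort of trials: per-trial metadata plus the raw yaw traces.

    ``meta`` has one row per trial (columns ``mouse, session, trial,
    block, speed, direction, static_pre, contrast, dot_radius, group,
    row``); ``traces[g]`` is a 2-D array (trials x samples) holding the
    traces of all trials with static-pre duration ``g`` seconds, whose
    motion onset is at sample ``60 * g``.
    """

    def __init__(self, meta: pd.DataFrame, traces: dict[int, np.ndarray], fs: float = FS):
        missing = set(_META_COLUMNS) - set(meta.columns)
        if missing:
            raise DataError(f"meta lacks columns: {sorted(missing)}")
        self.meta = meta.reset_index(drop=True)
        self.traces = {int(g): np.asarray(a, dtype=float) for g, a in traces.items()}
        self.fs = fs

    @property
    def n_trials(self) -> int:
        return len(self.meta)

    def t0_index(self, group: int) -> int:
        return int(round(group * self.fs))

    def get_trace(self, i: int) -> YawTrace:
        row = self.meta.iloc[i]
        samples = self.traces[int(row["group"])][int(row["row"])]
        cond = TrialCondition(
            speed=float(row["speed"]),
            direction=str(row["direction"]),
            static_pre=int(row["static_pre"]),
            contrast=float(row["contrast"]),
            dot_radius=float(row["dot_radius"]),
        )
        return YawTrace(
            samples,
            self.t0_index(int(row["group"])),
            cond,
            int(row["mouse"]),
            int(row["session"]),
            int(row["trial"]),
            self.fs,
        )

    def subset(self, mask: np.ndarray) -> "TrialDataset":
        """Dataset restricted to trials where ``mask`` is True (traces re-packed)."""
        mask = np.asarray(mask, dtype=bool)
        meta = self.meta.loc[mask].reset_index(drop=True).copy()
        traces: dict[int, np.ndarray] = {}
        new_rows = np.empty(len(meta), dtype=int)
        for g in sorted(meta["group"].unique()):
            sel = meta["group"] == g
            old_rows = meta.loc[sel, "row"].to_numpy(dtype=int)
            traces[int(g)] = self.traces[int(g)][old_rows]
            new_rows[sel.to_numpy()] = np.arange(sel.sum())
        meta["row"] = new_rows
        return TrialDataset(meta, traces, self.fs)

    # -- IO ----------------------------------------------------------------

    def write_csv(self, directory) -> None:
        """Write ``trials.csv`` (metadata) and ``samples.csv`` (tidy long form)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.meta.drop(columns=["group", "row"]).assign(
            trial_key=np.arange(self.n_trials)
        ).to_csv(directory / "trials.csv", index=False)
        parts = []
        for key in range(self.n_trials):
            row = self.meta.iloc[key]
            tr = self.traces[int(row["group"])][int(row["row"])]
            t = (np.arange(tr.size) - self.t0_index(int(row["group"]))) / self.fs
            parts.append(
                pd.DataFrame({"trial_key": key, "t_s": np.round(t, 6), "yaw_deg_s": tr})
            )
        pd.concat(parts, ignore_index=True).to_csv(
            directory / "samples.csv", index=False, float_format="%.10g"
        )

    @classmethod
    def read_csv(cls, directory, fs: float = FS) -> "TrialDataset":
        directory = Path(directory)
        meta = pd.read_csv(directory / "trials.csv")
        samples = pd.read_csv(directory / "samples.csv")
        meta = meta.sort_values("trial_key").reset_index(drop=True)
        meta["group"] = meta["static_pre"].astype(int)
        rows = np.empty(len(meta), dtype=int)
        traces: dict[int, list[np.ndarray]] = {}
        by_key = {k: g["yaw_deg_s"].to_numpy() for k, g in samples.groupby("trial_key", sort=True)}
        for i, row in meta.iterrows():
            g = int(row["group"])
            traces.setdefault(g, [])
            rows[i] = len(traces[g])
            traces[g].append(by_key[row["trial_key"]])
        meta["row"] = rows
        meta = meta.drop(columns=["trial_key"])
        return cls(meta, {g: np.vstack(v) for g, v in traces.items()}, fs)


def simulate_cohort(
    design: ExperimentDesign,
    n_mice: int = 6,
    cohort_spec: CohortSpec = CohortSpec(),
    rng: np.random.Generator | int | None = None,
    tuning: TuningModel | None = None,
    session_scale: Sequence[float] | None = None,
) -> tuple[TrialDataset, dict]:
    """Simulate a full cohort over all sessions of ``design``.

    Each mouse runs ``design.n_sessions`` sessions, each a fresh
    randomized interleaved schedule.  ``session_scale`` optionally
    multiplies response amplitude per session (e.g. to emulate a reflex
    that strengthens over the testing period).  Returns the dataset and a
    ground-truth record (tuning parameters, per-mouse parameters,
    session scaling) for parameter-recovery studies.

    Deterministic for a fixed integer seed or Generator state.
    """
    if n_mice < 1:
        raise ArgumentError("n_mice must be >= 1")
    gen = np.random.default_rng(rng)
    if tuning is None:
        tuning = default_tuning()
    if session_scale is None:
        session_scale = np.ones(design.n_sessions)
    session_scale = np.asarray(session_scale, dtype=float)
    if session_scale.shape != (design.n_sessions,):
        raise ArgumentError("session_scale must have one entry per session")

    mice = draw_cohort(n_mice, cohort_spec, gen)
    plateau_lookup = {c: tuning.plateau(c) for c in design.conditions}

    meta_rows: list[tuple] = []
    per_group_plateau: dict[int, list] = {1: [], 2: []}
    per_group_mouse: dict[int, list] = {1: [], 2: []}

    for m, mouse in enumerate(mice):
        for s in range(design.n_sessions):
            sched = make_schedule(design.conditions, design.repeats_per_session, gen, session_id=s)
            n_cond = len(design.conditions)
            for t, cond in enumerate(sched.trials):
                g = cond.static_pre
                sign = 1.0 if cond.direction == "right" else -1.0
                amp = sign * mouse.gain_multiplier * session_scale[s] * plateau_lookup[cond]
                row = len(per_group_plateau[g])
                meta_rows.append(
                    (m, s, t, t // n_cond, cond.speed, cond.direction, g, cond.contrast, cond.dot_radius, g, row)
                )
                per_group_plateau[g].append(amp)
                per_group_mouse[g].append(m)

    meta = pd.DataFrame(meta_rows, columns=_META_COLUMNS)

    # vectorized trace synthesis: response kernel depends only on (mouse, group)
    traces: dict[int, np.ndarray] = {}
    for g in (1, 2):
        n_tr = len(per_group_plateau[g])
        if n_tr == 0:
            continue
        timeline = TrialTimeline(static_pre=float(g))
        n = timeline.n_samples(FS)
        t0 = timeline.t0_index(FS)
        kernels = np.vstack(
            [step_response(n, t0, mouse.latency, mouse.time_constant, timeline.motion, FS) for mouse in mice]
        )
        amp = np.asarray(per_group_plateau[g])
        midx = np.asarray(per_group_mouse[g])
        arr = amp[:, None] * kernels[midx]
        drift_sd = np.array([mice[i].baseline_drift_sd for i in midx])
        noise_sd = np.array([mice[i].noise_sd for i in midx])
        arr += gen.normal(0.0, 1.0, size=n_tr)[:, None] * drift_sd[:, None]
        arr += gen.normal(0.0, 1.0, size=(n_tr, n)) * noise_sd[:, None]
        traces[g] = arr

    truth = {
        "tuning": tuning.to_dict(),
        "mice": [asdict(m) for m in mice],
        "session_scale": session_scale.tolist(),
        "experiment": design.name,
        "n_mice": n_mice,
    }
    return TrialDataset(meta, traces), truth
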