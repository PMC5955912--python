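"""Raw yaw traces -> baseline-corrected OLR traces and per-mouse OLR scalars.

The reduction chain, applied trial-wise and then aggregated:

1. smooth the 60 Hz yaw series with a 100 ms (6-sample) boxcar;
2. subtract the mean yaw of the final 500 ms (30 samples) before motion
   onset (removes the forward-running baseline of each trial);
3. the OLR scalar of a trial is the mean corrected yaw in the window
   1–2 s after motion onset (half-open, 60 samples);
4. per mouse, subtract the zero-speed response from every motion
   condition and fold matched left/right pairs
   (``((R - Z) + (-1)(L - Z)) / 2``), yielding one signed OLR per mouse
   and condition (positive = turning with the stimulus);
5. to prevent the strongest responders from dominating cohort means,
   z-score each mouse's condition curve and rescale by the pooled SD and
   mean of the population ("normalized" OLRs);
6. condition summaries: across-mouse mean, SEM (mouse is the unit of
   replication), one-sample t-test against 0, and OLR gain
   (OLR / stimulus speed, speed > 0 only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ArgumentError, DataError
from .synth import FS, TrialDataset, YawTrace

__all__ = [
    "CONDITION_KEYS",
    "SMOOTH_WINDOW_SAMPLES",
    "BASELINE_SAMPLES",
    "OLR_WINDOW_S",
    "boxcar_smooth",
    "smooth_yaw",
    "subtract_baseline",
    "olr_scalar",
    "baseline_correct_curves",
    "OLRTable",
    "trial_olr_frame",
    "compute_olr_table",
    "normalize_across_mice",
    "compute_gain",
    "olr_sem_table",
    "ttest_vs_zero",
    "mean_condition_traces",
]

CONDITION_KEYS = ["speed", "contrast", "dot_radius"]
SMOOTH_WINDOW_SAMPLES = 6  # 100 ms at 60 Hz
BASELINE_SAMPLES = 30  # 500 ms at 60 Hz
OLR_WINDOW_S = (1.0, 2.0)  # half-open [1, 2) after motion onset


def boxcar_smooth(x: np.ndarray, window: int = SMOOTH_WINDOW_SAMPLES) -> np.ndarray:
    """Centered moving average along the last axis.

    For an even ``window`` the span is split 3-left/2-right around each
    sample (window 6: indices ``i-3 .. i+2``); at the trace edges the
    window shrinks to the available samples.  A constant trace is passed
    unchanged everywhere, including the edges.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < window:
        raise DataError(f"trace of {n} samples is shorter than the {window}-sample window")
    left = window // 2
    right = window - left - 1  # inclusive right edge
    c = np.cumsum(x, axis=-1)
    zeros = np.zeros(x.shape[:-1] + (1,))
    c = np.concatenate([zeros, c], axis=-1)  # c[..., k] = sum of first k
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right + 1, n)
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def smooth_yaw(trace: YawTrace, window: int = SMOOTH_WINDOW_SAMPLES) -> YawTrace:
    """100 ms boxcar smoothing of one trial's yaw series."""
    return YawTrace(
        boxcar_smooth(trace.samples, window),
        trace.t0_index,
        trace.condition,
        trace.mouse_id,
        trace.session_id,
        trace.trial_id,
        trace.fs,
    )


def _baseline(arr: np.ndarray, t0_index: int, n_baseline: int = BASELINE_SAMPLES) -> np.ndarray:
    if t0_index < n_baseline:
        raise DataError(
            f"need {n_baseline} pre-onset samples (500 ms), trace has {t0_index}"
        )
    return arr[..., t0_index - n_baseline : t0_index].mean(axis=-1)


def subtract_baseline(trace: YawTrace, n_baseline: int = BASELINE_SAMPLES) -> YawTrace:
    """Subtract the mean yaw of the final 500 ms before motion onset."""
    b = _baseline(trace.samples, trace.t0_index, n_baseline)
    return YawTrace(
        trace.samples - b,
        trace.t0_index,
        trace.condition,
        trace.mouse_id,
        trace.session_id,
        trace.trial_id,
        trace.fs,
    )


def _olr_window(t0_index: int, fs: float = FS) -> tuple[int, int]:
    return t0_index + int(round(OLR_WINDOW_S[0] * fs)), t0_index + int(round(OLR_WINDOW_S[1] * fs))


def olr_scalar(trace: YawTrace) -> float:
    """Mean yaw in the half-open window 1–2 s after motion onset (deg/s)."""
    lo, hi = _olr_window(trace.t0_index, trace.fs)
    if trace.n_samples < hi:
        raise DataError("trace does not extend 2 s past motion onset")
    return float(trace.samples[lo:hi].mean())


def baseline_correct_curves(curves: dict) -> dict:
    """Zero-speed subtraction and left/right folding of per-condition mean traces.

    ``curves`` maps ``(speed, direction)`` to equal-length mean-trace
    arrays for one mouse; all zero-speed entries (any direction label)
    are pooled into the zero curve ``Z``.  For each speed ``s > 0`` the
    corrected trace is ``((R_s - Z) + (-1)*(L_s - Z)) / 2``; the
    zero-speed entry of the result is identically zero.  Raises
    :class:`DataError` if the zero-speed curve or a pair member is
    missing.
    """
    zero = [np.asarray(v, dtype=float) for (s, _d), v in curves.items() if s == 0]
    if not zero:
        raise DataError("zero-speed condition missing")
    z = np.mean(zero, axis=0)
    speeds = sorted({s for (s, _d) in curves if s > 0})
    out: dict[float, np.ndarray] = {0.0: np.zeros_like(z)}
    for s in speeds:
        if (s, "right") not in curves or (s, "left") not in curves:
            raise DataError(f"missing left/right pair member at speed {s}")
        r = np.asarray(curves[(s, "right")], dtype=float)
        l = np.asarray(curves[(s, "left")], dtype=float)
        out[float(s)] = ((r - z) - (l - z)) / 2.0
    return out


# ---------------------------------------------------------------------------
# Table-level pipeline


class OLRTable:
    """Per-mouse, per-condition OLR scalars (baseline-corrected, folded).

    ``data`` columns: ``mouse, speed, contrast, dot_radius, olr`` and,
    after :meth:`normalize`, ``olr_norm``.  The zero-speed rows are 0 by
    construction of the folding step.
    """

    def __init__(self, data: pd.DataFrame):
        missing = {"mouse", "olr", *CONDITION_KEYS} - set(data.columns)
        if missing:
            raise DataError(f"OLR table lacks columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)

    @property
    def n_mice(self) -> int:
        return self.data["mouse"].nunique()

    @property
    def normalized(self) -> bool:
        return "olr_norm" in self.data.columns

    def value_column(self) -> str:
        return "olr_norm" if self.normalized else "olr"

    def normalize(self) -> "OLRTable":
        return normalize_across_mice(self)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        return olr_sem_table(self, alpha=alpha)

    def points(self, drop_zero_speed: bool = True) -> pd.DataFrame:
        """Mouse x condition points (the bootstrap resampling units)."""
        df = self.data
        if drop_zero_speed:
            df = df[df["speed"] > 0]
        return df.reset_index(drop=True)


def trial_olr_frame(dataset: TrialDataset, smooth: bool = True) -> pd.DataFrame:
    """Per-trial OLR scalars: smooth, baseline-subtract, average the 1–2 s window."""
    olr = np.empty(dataset.n_trials)
    for g, arr in dataset.traces.items():
        t0 = dataset.t0_index(g)
        a = boxcar_smooth(arr) if smooth else np.asarray(arr, dtype=float)
        a = a - _baseline(a, t0)[:, None]
        lo, hi = _olr_window(t0, dataset.fs)
        if a.shape[-1] < hi:
            raise DataError("traces do not extend 2 s past motion onset")
        vals = a[:, lo:hi].mean(axis=1)
        rows = dataset.meta.loc[dataset.meta["group"] == g, "row"].to_numpy(dtype=int)
        olr[dataset.meta["group"].to_numpy() == g] = vals[rows]
    out = dataset.meta.drop(columns=["group", "row"]).copy()
    out["olr"] = olr
    return out


def fold_trial_olrs(trials: pd.DataFrame) -> OLRTable:
    """Per-mouse condition means, zero-speed subtraction and left/right folding.

    Input: per-trial OLRs (columns ``mouse, speed, direction, contrast,
    dot_radius, olr``); the two static-pre onsets are pooled as repeats.
    """
    keys = ["mouse", "contrast", "dot_radius"]
    mean = (
        trials.groupby(keys + ["speed", "direction"], sort=True)["olr"].mean().reset_index()
    )
    rows = []
    for key_vals, grp in mean.groupby(keys, sort=True):
        zero = grp.loc[grp["speed"] == 0, "olr"]
        if zero.empty:
            raise DataError(f"zero-speed condition missing for {dict(zip(keys, key_vals))}")
        z = zero.mean()
        rows.append(dict(zip(keys, key_vals)) | {"speed": 0.0, "olr": 0.0})
        for s in sorted(grp.loc[grp["speed"] > 0, "speed"].unique()):
            r = grp.loc[(grp["speed"] == s) & (grp["direction"] == "right"), "olr"]
            l = grp.loc[(grp["speed"] == s) & (grp["direction"] == "left"), "olr"]
            if r.empty or l.empty:
                raise DataError(f"missing left/right pair member at speed {s}")
            rows.append(
                dict(zip(keys, key_vals))
                | {"speed": float(s), "olr": ((r.iloc[0] - z) - (l.iloc[0] - z)) / 2.0}
            )
    df = pd.DataFrame(rows)[["mouse", "speed", "contrast", "dot_radius", "olr"]]
    return OLRTable(df)


def compute_olr_table(dataset: TrialDataset, smooth: bool = True) -> OLRTable:
    """Full per-trial reduction and per-mouse folding for a dataset."""
    return fold_trial_olrs(trial_olr_frame(dataset, smooth=smooth))


def normalize_across_mice(table: OLRTable) -> OLRTable:
    """Equalize per-mouse response magnitude, preserving the population scale.

    Each mouse's condition vector (speed > 0 conditions; the zero-speed
    entries are identically 0 and stay 0) is z-scored and rescaled by the
    population SD and mean — the across-mouse averages of the per-mouse
    curve SDs and means (ddof=0).  After normalization every mouse's
    curve has that common mean and SD, so no mouse dominates the
    condition means, while the pooled mean of the table (and hence curve
    amplitude in deg/s) is preserved.

    Rescaling by the pooled SD of all mouse x condition values would
    instead stretch every curve by the between-mouse variance ratio and
    inflate peak-height estimates; the average-statistics rescale is the
    amplitude-preserving convention and the one used throughout this
    package.
    """
    df = table.data.copy()
    nz = df["speed"] > 0
    if df["mouse"].nunique() < 2 or df.loc[nz].groupby("mouse").size().min() < 2:
        raise DataError("normalization needs >= 2 mice and >= 2 nonzero-speed conditions")
    groups = list(df.loc[nz].groupby("mouse").groups.items())
    means = {}
    sds = {}
    for mouse, idx in groups:
        x = df.loc[idx, "olr"].to_numpy()
        means[mouse], sds[mouse] = x.mean(), x.std(ddof=0)
        if sds[mouse] == 0:
            raise DataError("a mouse has zero variance across conditions")
    pop_mean = float(np.mean(list(means.values())))
    pop_sd = float(np.mean(list(sds.values())))
    norm = np.zeros(len(df))
    for mouse, idx in groups:
        x = df.loc[idx, "olr"].to_numpy()
        norm[df.index.get_indexer(idx)] = (x - means[mouse]) / sds[mouse] * pop_sd + pop_mean
    df["olr_norm"] = norm
    return OLRTable(df)


def compute_gain(olr: float, speed: float) -> float:
    """OLR gain: OLR divided by the stimulus speed that evoked it (speed > 0)."""
    if speed <= 0:
        raise ArgumentError("gain is defined only for speed > 0")
    return olr / speed


def ttest_vs_zero(values: np.ndarray, alpha: float = 0.05) -> tuple[float, bool, bool]:
    """Two-sided one-sample t-test against 0.

    Returns ``(p_value, significant, degenerate)``; zero-variance input
    is flagged degenerate (p set to 1 if the common value is 0, else 0).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DataError("t-test needs >= 2 mice")
    if values.std(ddof=1) == 0:
        p = 1.0 if values.mean() == 0 else 0.0
        return p, p < alpha, True
    t, p = stats.ttest_1samp(values, 0.0)
    return float(p), bool(p < alpha), False


def olr_sem_table(table: OLRTable, alpha: float = 0.05) -> pd.DataFrame:
    """Across-mouse condition summary: mean, SEM, t-test flag, gain.

    The mouse is the unit of replication; SEM uses the sample SD
    (ddof=1) over per-mouse OLRs.  Gain columns are NaN at speed 0.
    """
    if table.n_mice < 2:
        raise DataError("SEM across mice needs >= 2 mice")
    val = table.value_column()
    rows = []
    for cond, grp in table.data.groupby(CONDITION_KEYS, sort=True):
        x = grp[val].to_numpy()
        p, sig, degen = ttest_vs_zero(x, alpha) if x.size >= 2 else (np.nan, False, True)
        mean = x.mean()
        sem = x.std(ddof=1) / np.sqrt(x.size)
        speed = cond[CONDITION_KEYS.index("speed")]
        rows.append(
            dict(zip(CONDITION_KEYS, cond))
            | {
                "mean_olr": mean,
                "sem": sem,
                "n": x.size,
                "p_vs_zero": p,
                "significant": sig,
                "degenerate": degen,
                "gain_mean": mean / speed if speed > 0 else np.nan,
                "gain_sem": sem / speed if speed > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def mean_condition_traces(dataset: TrialDataset, smooth: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """Per mouse x condition mean traces aligned on motion onset.

    Traces are cropped to a common window of 1 s before to 3 s after
    motion onset (240 samples, onset at index 60), smoothed and
    baseline-subtracted trial-wise, then averaged within mouse x
    (speed, direction, contrast, dot_radius).  Returns an index frame
    and the aligned trace matrix (one row per index entry).
    """
    fs = dataset.fs
    pre = int(round(1.0 * fs))
    post = int(round(3.0 * fs))
    aligned = np.empty((dataset.n_trials, pre + post))
    for g, arr in dataset.traces.items():
        t0 = dataset.t0_index(g)
        a = boxcar_smooth(arr) if smooth else np.asarray(arr, dtype=float)
        a = a - _baseline(a, t0)[:, None]
        sel = (dataset.meta["group"] == g).to_numpy()
        rows = dataset.meta.loc[sel, "row"].to_numpy(dtype=int)
        aligned[sel] = a[rows, t0 - pre : t0 + post]
    keys = ["mouse", "speed", "direction", "contrast", "dot_radius"]
    meta = dataset.meta[keys]
    index_rows = []
    means = []
    for cond, idx in meta.groupby(keys, sort=True).groups.items():
        index_rows.append(dict(zip(keys, cond)))
        means.append(aligned[meta.index.get_indexer(idx)].mean(axis=0))
    return pd.DataFrame(index_rows), np.vstack(means)
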