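"""Experiment-level analysis: dataset -> OLR table -> tuning fit -> bootstrap peaks.

:class:`OLRAnalysis` is the model object for a whole experiment: build it
from a :class:`~olrkit.synth.TrialDataset` (simulated or rig export in
the same schema) and call :meth:`~OLRAnalysis.fit` to run the full chain

    per-trial OLR -> fold -> normalize -> condition summary ->
    weighted polynomial fit (order chosen by stepwise F-tests) ->
    bootstrap peak with 95% intervals -> same for OLR gain,

returning an :class:`OLRResults` with a text ``summary()`` and plotting
helpers.  :func:`session_split_analysis` re-runs the chain on two
partitions of the trials (within-session halves, or early vs late
sessions) and compares the peak confidence regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, DataError
from .fitting import (
    FTestResult,
    PeakEstimate,
    PeakLocation,
    PolynomialResults,
    WeightedPolynomial,
    WeightedPolySurface,
    bootstrap_peak,
    nested_f_test,
)
from .preprocess import CONDITION_KEYS, OLRTable, compute_olr_table, olr_sem_table
from .synth import TrialDataset

__all__ = ["OLRAnalysis", "OLRResults", "SplitResult", "session_split_analysis"]


def _detect_factor(meta: pd.DataFrame) -> str | None:
    if meta["contrast"].nunique() > 1:
        return "contrast"
    if meta["dot_radius"].nunique() > 1:
        return "dot_radius"
    return None


class OLRAnalysis:
    """Analysis model for one experiment's trial dataset.

    Parameters
    ----------
    dataset : TrialDataset
        Trials of a single experiment (one varied factor besides speed,
        or none for the speed experiment).
    boot : int
        Bootstrap replicates for peak estimation (200 by default).
    alpha : float
        Significance level of the stepwise model-order F-tests.
    smooth : bool
        Apply the 100 ms boxcar before reduction.
    """

    def __init__(self, dataset: TrialDataset, boot: int = 200, alpha: float = 0.05, smooth: bool = True):
        self.dataset = dataset
        self.boot = int(boot)
        self.alpha = float(alpha)
        self.smooth = bool(smooth)
        self.factor = _detect_factor(dataset.meta)

    @classmethod
    def from_csv(cls, directory, **kwargs) -> "OLRAnalysis":
        return cls(TrialDataset.read_csv(directory), **kwargs)

    # -- model-order ladders ------------------------------------------------

    def _select_1d(self, y, x, se, max_degree: int):
        current = WeightedPolynomial(y, x, se, degree=1).fit()
        trail: list[FTestResult] = []
        for d in range(2, max_degree + 1):
            larger = WeightedPolynomial(y, x, se, degree=d).fit()
            ft = nested_f_test(current, larger)
            trail.append(ft)
            if ft.pvalue < self.alpha:
                current = larger
            else:
                break
        return current, trail

    def _select_surface(self, y, x1, x2, se):
        """Stepwise poly22 -> (poly23 | poly32) -> poly33.

        Both 9-parameter extensions of the biquadratic are tested; if
        either improves significantly the one with the smaller p-value is
        kept, then the full bicubic is tested against it.
        """
        current = WeightedPolySurface(y, x1, x2, se, order=(2, 2)).fit()
        trail: list[FTestResult] = []
        best = None
        for order in ((2, 3), (3, 2)):
            larger = WeightedPolySurface(y, x1, x2, se, order=order).fit()
            ft = nested_f_test(current, larger)
            trail.append(ft)
            if ft.pvalue < self.alpha and (best is None or ft.pvalue < best[0].pvalue):
                best = (ft, larger)
        if best is not None:
            current = best[1]
            full = WeightedPolySurface(y, x1, x2, se, order=(3, 3)).fit()
            ft = nested_f_test(current, full)
            trail.append(ft)
            if ft.pvalue < self.alpha:
                current = full
        return current, trail

    # -- fitting -------------------------------------------------------------

    def fit(self, seed: int | np.random.Generator | None = None) -> "OLRResults":
        gen = np.random.default_rng(seed)
        table = compute_olr_table(self.dataset, smooth=self.smooth).normalize()
        summary = olr_sem_table(table, alpha=self.alpha)
        nz = summary[summary["speed"] > 0]
        speeds = np.sort(nz["speed"].unique())
        speed_domain = (float(speeds.min()), float(speeds.max()))

        points = table.points()
        points = points.assign(gain=points["olr_norm"] / points["speed"])

        if self.factor is None:
            olr_fit, olr_trail = self._select_1d(
                nz["mean_olr"].to_numpy(), nz["speed"].to_numpy(), nz["sem"].to_numpy(), 3
            )
            olr_boot = bootstrap_peak(
                points, olr_fit.model.degree, speed_domain, value="olr_norm", B=self.boot, rng=gen
            )
            gain_fit, gain_trail = self._select_1d(
                nz["gain_mean"].to_numpy(), nz["speed"].to_numpy(), nz["gain_sem"].to_numpy(), 4
            )
            gain_boot = bootstrap_peak(
                points, gain_fit.model.degree, speed_domain, value="gain", B=self.boot, rng=gen
            )
            domain = (speed_domain,)
        else:
            f = nz[self.factor].to_numpy()
            fv = np.sort(nz[self.factor].unique())
            fdomain = (float(fv.min()), float(fv.max()))
            domain = (fdomain, speed_domain)
            olr_fit, olr_trail = self._select_surface(
                nz["mean_olr"].to_numpy(), f, nz["speed"].to_numpy(), nz["sem"].to_numpy()
            )
            olr_boot = bootstrap_peak(
                points,
                olr_fit.model.order,
                domain,
                value="olr_norm",
                factor=self.factor,
                B=self.boot,
                rng=gen,
            )
            gain_fit, gain_trail = self._select_surface(
                nz["gain_mean"].to_numpy(), f, nz["speed"].to_numpy(), nz["gain_sem"].to_numpy()
            )
            gain_boot = bootstrap_peak(
                points,
                gain_fit.model.order,
                domain,
                value="gain",
                factor=self.factor,
                B=self.boot,
                rng=gen,
            )

        peak_domain = domain[0] if self.factor is None else domain
        return OLRResults(
            factor=self.factor,
            table=table,
            condition_summary=summary,
            olr_fit=olr_fit,
            olr_trail=olr_trail,
            olr_peak=olr_fit.peak(peak_domain),
            olr_boot=olr_boot,
            gain_fit=gain_fit,
            gain_trail=gain_trail,
            gain_peak=gain_fit.peak(peak_domain),
            gain_boot=gain_boot,
            domain=peak_domain,
        )


@dataclass
class OLRResults:
    """Fitted results of one experiment.

    ``olr_*`` describe the OLR tuning (deg/s); ``gain_*`` the OLR gain
    (OLR / stimulus speed).  Peaks carry both the point fit on the
    condition means and the bootstrap distribution over mouse x condition
    resamples.
    """

    factor: str | None
    table: OLRTable
    condition_summary: pd.DataFrame
    olr_fit: PolynomialResults
    olr_trail: list[FTestResult]
    olr_peak: PeakLocation
    olr_boot: PeakEstimate
    gain_fit: PolynomialResults
    gain_trail: list[FTestResult]
    gain_peak: PeakLocation
    gain_boot: PeakEstimate
    domain: tuple

    def summary(self) -> str:
        kind = "speed tuning" if self.factor is None else f"{self.factor} x speed surface"
        lines = [f"OLR analysis ({kind}; {self.table.n_mice} mice)"]
        lines.append("-- OLR fit --")
        lines.append(self.olr_fit.summary())
        for ft in self.olr_trail:
            lines.append(f"  model ladder: {ft}")
        lines.append(
            f"  peak of fit at {tuple(round(v, 3) for v in self.olr_peak.location)}"
            f" height {self.olr_peak.height:.3f}"
            + (" (boundary)" if self.olr_peak.on_boundary else "")
        )
        lines.append(self.olr_boot.summary())
        lines.append("-- OLR gain fit --")
        lines.append(self.gain_fit.summary())
        for ft in self.gain_trail:
            lines.append(f"  model ladder: {ft}")
        lines.append(
            f"  peak of fit at {tuple(round(v, 3) for v in self.gain_peak.location)}"
            f" height {self.gain_peak.height:.3f}"
            + (" (boundary)" if self.gain_peak.on_boundary else "")
        )
        lines.append(self.gain_boot.summary())
        return "\n".join(lines)

    # -- plotting (lazy matplotlib import) ---------------------------------

    def plot_tuning(self, ax=None):
        """Mean OLR vs speed (or factor, per speed) with SEM bars and the fit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.condition_summary
        nz = s[s["speed"] > 0]
        if self.factor is None:
            ax.errorbar(nz["speed"], nz["mean_olr"], yerr=nz["sem"], fmt="o", capsize=3)
            grid = np.linspace(self.domain[0], self.domain[1], 200)
            ax.plot(grid, self.olr_fit.predict(grid))
            ax.set_xlabel("stimulus speed (deg/s)")
        else:
            for sp, grp in nz.groupby("speed"):
                ax.errorbar(grp[self.factor], grp["mean_olr"], yerr=grp["sem"], fmt="o-", capsize=3, label=f"{sp:g} deg/s")
            ax.legend(title="speed")
            ax.set_xlabel(self.factor)
        ax.set_ylabel("OLR (deg/s)")
        return ax


@dataclass
class SplitResult:
    """Consistency comparison of two trial partitions."""

    split: str
    labels: tuple[str, str]
    results: tuple[OLRResults, OLRResults]
    #: per-axis overlap of the two 95% peak-location intervals (OLR peak)
    peak_ci_overlap: np.ndarray
    #: mean OLR of partition 2 / partition 1 over nonzero-speed conditions
    amplitude_ratio: float

    def summary(self) -> str:
        axes = ["factor", "speed"][-len(self.peak_ci_overlap) :]
        overlap = ", ".join(f"{a}: {'yes' if o else 'no'}" for a, o in zip(axes, self.peak_ci_overlap))
        return (
            f"Split '{self.split}' ({self.labels[1]} vs {self.labels[0]}): "
            f"amplitude ratio {self.amplitude_ratio:.3f}; peak-CI overlap {overlap}"
        )


def _partition_masks(dataset: TrialDataset, split: str) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    meta = dataset.meta
    if split == "within_session_half":
        first = np.zeros(len(meta), dtype=bool)
        for (_m, _s), idx in meta.groupby(["mouse", "session"]).groups.items():
            trials = meta.loc[idx, "trial"]
            cut = trials.max() + 1
            first[meta.index.get_indexer(idx)] = (trials < cut / 2).to_numpy()
        return first, ~first, ("first_half", "second_half")
    if split == "early_vs_late_sessions":
        early = np.zeros(len(meta), dtype=bool)
        for _m, idx in meta.groupby("mouse").groups.items():
            sess = meta.loc[idx, "session"]
            n_sess = sess.nunique()
            if n_sess < 2:
                raise DataError("early/late split needs >= 2 sessions per mouse")
            mid = sorted(sess.unique())[n_sess // 2]
            early[meta.index.get_indexer(idx)] = (sess < mid).to_numpy()
        return early, ~early, ("early_sessions", "late_sessions")
    raise ArgumentError(f"unknown split {split!r}")


def session_split_analysis(
    dataset: TrialDataset,
    split: str,
    boot: int = 200,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> SplitResult:
    """Re-run the full pipeline on two partitions of the trials.

    ``split`` is ``"within_session_half"`` (first vs second half of each
    session's trial sequence) or ``"early_vs_late_sessions"`` (sessions
    before the per-mouse middle session vs on/after it).  Each partition
    goes through preprocessing, normalization, fitting and bootstrap peak
    estimation; the result reports whether the two 95% peak-location
    intervals overlap on each axis and the amplitude ratio of the two
    mean tuning curves.
    """
    gen = np.random.default_rng(seed)
    m1, m2, labels = _partition_masks(dataset, split)
    if not m1.any() or not m2.any():
        raise DataError("partition left one half empty")
    results = []
    for mask in (m1, m2):
        sub = dataset.subset(mask)
        results.append(OLRAnalysis(sub, boot=boot, alpha=alpha).fit(seed=gen))
    r1, r2 = results
    ci1, ci2 = r1.olr_boot.ci_location, r2.olr_boot.ci_location
    overlap = (ci1[0] <= ci2[1]) & (ci2[0] <= ci1[1])
    s1 = r1.condition_summary
    s2 = r2.condition_summary
    a1 = s1.loc[s1["speed"] > 0, "mean_olr"].mean()
    a2 = s2.loc[s2["speed"] > 0, "mean_olr"].mean()
    return SplitResult(split, labels, (r1, r2), np.atleast_1d(overlap), a2 / a1)
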