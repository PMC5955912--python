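"""Simulation studies: F-test calibration, model-order selection, parameter recovery.

These routines quantify the statistical behaviour of the pipeline under
known ground truth.  They back the package's validation suite and the
reproduction script, and are reusable for power analyses at other
problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import make_design
from .fitting import WeightedPolynomial, nested_f_test
from .pipeline import OLRAnalysis, session_split_analysis
from .synth import CohortSpec, TuningModel, default_tuning, simulate_cohort

__all__ = [
    "ftest_type1_error",
    "model_selection_rate",
    "peak_recovery_study",
    "split_consistency_study",
]

_SPEEDS = np.arange(9.0, 73.0, 9.0)  # the 8 nonzero speeds of the speed experiment


def ftest_type1_error(
    n_sims: int = 2000,
    noise_sd: float = 1.0,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Empirical type-I error of the nested F-test under a true quadratic.

    Simulates mean-OLR curves from a quadratic truth plus i.i.d. Gaussian
    noise at the 8 nonzero speeds, tests quadratic vs cubic, and returns
    the fraction of simulations with p below ``alpha``.  Under correct
    calibration this converges to ``alpha``.
    """
    gen = np.random.default_rng(rng)
    truth = default_tuning()(_SPEEDS)
    se = np.full(_SPEEDS.size, noise_sd)
    hits = 0
    for _ in range(n_sims):
        y = truth + gen.normal(0.0, noise_sd, size=_SPEEDS.size)
        small = WeightedPolynomial(y, _SPEEDS, se, degree=2).fit()
        large = WeightedPolynomial(y, _SPEEDS, se, degree=3).fit()
        if nested_f_test(small, large).pvalue < alpha:
            hits += 1
    return hits / n_sims


def model_selection_rate(
    n_sims: int = 500,
    noise_sd: float = 1.5,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Fraction of simulations in which the ladder line->quadratic->cubic picks the true quadratic."""
    gen = np.random.default_rng(rng)
    truth = default_tuning()(_SPEEDS)
    se = np.full(_SPEEDS.size, noise_sd)
    correct = 0
    for _ in range(n_sims):
        y = truth + gen.normal(0.0, noise_sd, size=_SPEEDS.size)
        current = WeightedPolynomial(y, _SPEEDS, se, degree=1).fit()
        selected = 1
        for d in (2, 3):
            larger = WeightedPolynomial(y, _SPEEDS, se, degree=d).fit()
            if nested_f_test(current, larger).pvalue < alpha:
                current, selected = larger, d
            else:
                break
        if selected == 2:
            correct += 1
    return correct / n_sims


@dataclass
class RecoveryReplicate:
    peak_speed_covered: bool
    peak_olr_covered: bool
    zero_speed_all_zero: bool
    boot_mean_speed: float
    boot_mean_olr: float


def peak_recovery_study(
    n_replicates: int = 50,
    n_mice: int = 6,
    true_peak_speed: float = 57.2,
    true_peak_olr: float = 35.0,
    boot: int = 200,
    cohort_spec: CohortSpec = CohortSpec(),
    rng: np.random.Generator | int | None = None,
) -> dict:
    """End-to-end recovery of a known tuning peak at full study scale.

    Each replicate simulates a fresh cohort on the speed-experiment
    design (``n_mice`` mice, 70 presentations per condition), runs the
    full pipeline (preprocess -> fold -> normalize -> weighted quadratic
    fit -> ``boot``-sample bootstrap) and checks whether the true peak
    speed and height fall inside the bootstrap 95% percentile intervals,
    and whether the folded zero-speed OLRs are exactly zero.
    """
    gen = np.random.default_rng(rng)
    design = make_design("speed")
    tuning = TuningModel(peak_speed=true_peak_speed, peak_olr=true_peak_olr)
    reps: list[RecoveryReplicate] = []
    for _ in range(n_replicates):
        dataset, _truth = simulate_cohort(design, n_mice, cohort_spec, gen, tuning=tuning)
        res = OLRAnalysis(dataset, boot=boot).fit(seed=gen)
        ci = res.olr_boot.ci_location
        hci = res.olr_boot.ci_height
        zero_rows = res.table.data.loc[res.table.data["speed"] == 0, "olr"]
        reps.append(
            RecoveryReplicate(
                peak_speed_covered=bool(ci[0, -1] <= true_peak_speed <= ci[1, -1]),
                peak_olr_covered=bool(hci[0] <= true_peak_olr <= hci[1]),
                zero_speed_all_zero=bool(np.all(zero_rows == 0.0)),
                boot_mean_speed=float(res.olr_boot.mean_location[-1]),
                boot_mean_olr=float(res.olr_boot.mean_height),
            )
        )
    return {
        "replicates": reps,
        "speed_coverage": np.mean([r.peak_speed_covered for r in reps]),
        "olr_coverage": np.mean([r.peak_olr_covered for r in reps]),
        "zero_speed_always_zero": all(r.zero_speed_all_zero for r in reps),
        "mean_boot_peak_speed": float(np.mean([r.boot_mean_speed for r in reps])),
        "mean_boot_peak_olr": float(np.mean([r.boot_mean_olr for r in reps])),
    }


def split_consistency_study(
    late_gain_factor: float = 1.0,
    n_mice: int = 6,
    boot: int = 200,
    cohort_spec: CohortSpec = CohortSpec(),
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Within-session and early/late-session consistency on a simulated cohort.

    With ``late_gain_factor`` = 1 the cohort is stationary and both
    splits should show overlapping peak confidence intervals and
    amplitude ratios near 1.  With ``late_gain_factor`` = 2 the response
    doubles in the later half of the sessions: the late curve should be
    about twice the early one while the peak-speed intervals still
    overlap (the tuning shape does not change).
    """
    gen = np.random.default_rng(rng)
    design = make_design("speed")
    scale = np.ones(design.n_sessions)
    scale[design.n_sessions // 2 :] = late_gain_factor
    dataset, _ = simulate_cohort(design, n_mice, cohort_spec, gen, session_scale=scale)
    within = session_split_analysis(dataset, "within_session_half", boot=boot, seed=gen)
    across = session_split_analysis(dataset, "early_vs_late_sessions", boot=boot, seed=gen)
    return {
        "within": within,
        "across": across,
        "within_overlap_speed": bool(within.peak_ci_overlap[-1]),
        "across_overlap_speed": bool(across.peak_ci_overlap[-1]),
        "within_amplitude_ratio": within.amplitude_ratio,
        "across_amplitude_ratio": across.amplitude_ratio,
    }
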