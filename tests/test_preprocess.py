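"""Trace reduction: smoothing, baseline, OLR scalars, folding, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from olrkit.exceptions import ArgumentError, DataError
from olrkit.preprocess import (
    OLRTable,
    baseline_correct_curves,
    boxcar_smooth,
    compute_gain,
    compute_olr_table,
    mean_condition_traces,
    normalize_across_mice,
    olr_scalar,
    olr_sem_table,
    smooth_yaw,
    subtract_baseline,
    ttest_vs_zero,
)
from olrkit.synth import YawTrace


def _trace(samples, t0=60):
    return YawTrace(np.asarray(samples, dtype=float), t0)


class TestBoxcar:
    def test_constant_trace_unchanged(self):
        x = np.full(100, 3.7)
        np.testing.assert_allclose(boxcar_smooth(x), x)

    def test_impulse_spreads_to_six_samples_of_one_sixth(self):
        x = np.zeros(100)
        x[50] = 1.0
        y = boxcar_smooth(x)
        # direct convolution oracle: window spans i-3 .. i+2
        conv = np.convolve(x, np.ones(6) / 6, mode="full")
        np.testing.assert_allclose(y[10:90], conv[12:92])
        assert np.count_nonzero(y) == 6
        np.testing.assert_allclose(y[y > 0], 1 / 6)

    def test_white_noise_variance_reduced_sixfold(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200_000)
        y = boxcar_smooth(x)
        assert np.var(y[10:-10]) == pytest.approx(1 / 6, rel=0.02)

    def test_too_short_trace_rejected(self):
        with pytest.raises(DataError):
            boxcar_smooth(np.zeros(5))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(-5, 5), offset=st.floats(-10, 10))
    def test_linearity_under_scaling_and_offset(self, scale, offset):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        lhs = boxcar_smooth(scale * x + offset)
        rhs = scale * boxcar_smooth(x) + offset
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestBaseline:
    def test_constant_offset_removed_exactly(self):
        tr = _trace(np.full(240, 7.5))
        out = subtract_baseline(tr)
        np.testing.assert_allclose(out.samples, 0.0)

    def test_preonset_window_mean_is_zero(self):
        rng = np.random.default_rng(2)
        tr = _trace(rng.normal(size=240))
        out = subtract_baseline(tr)
        assert out.samples[30:60].mean() == pytest.approx(0.0, abs=1e-12)

    def test_ramp_centered_at_baseline_centroid(self):
        # for input a*t the output vanishes at the centroid of the baseline window
        a, fs = 2.0, 60.0
        t = np.arange(240) / fs
        out = subtract_baseline(_trace(a * t))
        centroid = (60 - 15.5) / fs
        np.testing.assert_allclose(out.samples, a * (t - centroid), atol=1e-12)

    def test_insufficient_preonset_samples(self):
        with pytest.raises(DataError):
            subtract_baseline(_trace(np.zeros(240), t0=20))


class TestOLRScalar:
    def test_zero_trace(self):
        assert olr_scalar(_trace(np.zeros(240))) == 0.0

    def test_constant_window_value(self):
        x = np.zeros(240)
        x[120:180] = 29.5
        assert olr_scalar(_trace(x)) == pytest.approx(29.5)

    def test_ramp_reads_window_centroid(self):
        a, fs = 3.0, 60.0
        t = np.arange(300) / fs
        tr = _trace(a * t, t0=120)
        # mean over the 60 samples [t0+1, t0+2): centroid t0 + 1 + 59/120 s
        assert olr_scalar(tr) == pytest.approx(a * (2.0 + 1.0 + 59 / 120))

    def test_short_trace_rejected(self):
        with pytest.raises(DataError):
            olr_scalar(_trace(np.zeros(150)))

    def test_smooth_yaw_keeps_metadata(self):
        tr = _trace(np.arange(240.0))
        out = smooth_yaw(tr)
        assert out.t0_index == tr.t0_index and out.n_samples == 240


class TestFolding:
    def test_antisymmetric_pair_with_zero_reference(self):
        rng = np.random.default_rng(3)
        r = rng.normal(size=240)
        curves = {(36.0, "right"): r, (36.0, "left"): -r, (0.0, "right"): np.zeros(240), (0.0, "left"): np.zeros(240)}
        out = baseline_correct_curves(curves)
        np.testing.assert_allclose(out[36.0], r)
        np.testing.assert_allclose(out[0.0], 0.0)

    def test_all_conditions_equal_zero_speed_gives_zero_curves(self):
        base = np.sin(np.linspace(0, 5, 240))
        curves = {(s, d): base for s in (0.0, 18.0, 36.0) for d in ("left", "right")}
        out = baseline_correct_curves(curves)
        for s in (0.0, 18.0, 36.0):
            np.testing.assert_allclose(out[s], 0.0, atol=1e-12)

    def test_common_additive_drift_cancels(self):
        rng = np.random.default_rng(4)
        signal = rng.normal(size=240)
        drift = 0.8 * np.ones(240)
        curves = {
            (18.0, "right"): signal + drift,
            (18.0, "left"): -signal + drift,
            (0.0, "right"): drift,
            (0.0, "left"): drift,
        }
        np.testing.assert_allclose(baseline_correct_curves(curves)[18.0], signal, atol=1e-12)

    def test_missing_pair_member(self):
        with pytest.raises(DataError):
            baseline_correct_curves({(18.0, "right"): np.zeros(10), (0.0, "left"): np.zeros(10)})

    def test_missing_zero_speed(self):
        with pytest.raises(DataError):
            baseline_correct_curves({(18.0, "right"): np.zeros(10), (18.0, "left"): np.zeros(10)})

    def test_noise_free_cohort_recovers_plateaus(self, quiet_cohort, tuning):
        dataset, truth = quiet_cohort
        table = compute_olr_table(dataset)
        gains = {i: m["gain_multiplier"] for i, m in enumerate(truth["mice"])}
        df = table.data[table.data["speed"] > 0]
        expected = df.apply(lambda r: gains[r["mouse"]] * tuning(r["speed"]), axis=1)
        np.testing.assert_allclose(df["olr"], expected, rtol=2e-3, atol=0.05)

    def test_zero_speed_rows_identically_zero(self, small_cohort):
        dataset, _ = small_cohort
        table = compute_olr_table(dataset)
        assert (table.data.loc[table.data["speed"] == 0, "olr"] == 0.0).all()


def _table(values: dict[int, np.ndarray], speeds=None) -> OLRTable:
    speeds = np.asarray(speeds if speeds is not None else 9.0 * np.arange(1, 1 + len(next(iter(values.values())))))
    rows = []
    for mouse, vals in values.items():
        for s, v in zip(speeds, vals):
            rows.append({"mouse": mouse, "speed": s, "contrast": 0.68, "dot_radius": 1.4, "olr": v})
    return OLRTable(pd.DataFrame(rows))


class TestNormalization:
    def test_identical_mice_left_unchanged(self):
        v = np.array([1.0, 4.0, 9.0, 7.0])
        t = normalize_across_mice(_table({0: v, 1: v}))
        np.testing.assert_allclose(t.data["olr_norm"], t.data["olr"])

    def test_scaled_mouse_contributes_equally_after(self):
        v = np.array([1.0, 4.0, 9.0, 7.0])
        t = normalize_across_mice(_table({0: v, 1: 3 * v}))
        sds = t.data.groupby("mouse")["olr_norm"].std(ddof=0)
        assert sds.iloc[0] == pytest.approx(sds.iloc[1])
        means = t.data.groupby("mouse")["olr_norm"].mean()
        assert means.iloc[0] == pytest.approx(means.iloc[1])

    def test_pooled_mean_preserved(self):
        rng = np.random.default_rng(5)
        t0 = _table({m: rng.normal(10, 3, size=6) for m in range(4)})
        t1 = normalize_across_mice(t0)
        assert t1.data["olr_norm"].mean() == pytest.approx(t0.data["olr"].mean())

    def test_pure_gain_spread_collapses_to_common_curve(self):
        v = np.array([2.0, 5.0, 9.0, 8.0])
        t = normalize_across_mice(_table({0: 0.5 * v, 1: v, 2: 1.8 * v}))
        wide = t.data.pivot(index="mouse", columns="speed", values="olr_norm")
        np.testing.assert_allclose(wide.to_numpy(), np.tile(wide.iloc[0], (3, 1)), rtol=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            normalize_across_mice(_table({0: np.array([1.0, 2.0])}))
        with pytest.raises(DataError):
            normalize_across_mice(_table({0: np.array([1.0, 1.0]), 1: np.array([1.0, 2.0])}))


class TestGainAndSummary:
    def test_gain_values(self):
        assert compute_gain(29.5, 36.4) == pytest.approx(0.81, abs=0.005)
        assert compute_gain(0.0, 36.0) == 0.0
        assert compute_gain(36.0, 36.0) == 1.0
        with pytest.raises(ArgumentError):
            compute_gain(1.0, 0.0)

    def test_sem_hand_computation(self):
        t = _table({0: np.array([1.0, 2.0]), 1: np.array([3.0, 2.0])})
        s = olr_sem_table(t)
        row = s[s["speed"] == 9.0].iloc[0]
        assert row["mean_olr"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0)  # sd of {1,3} / sqrt(2)
        assert row["n"] == 2

    def test_identical_mice_sem_zero(self):
        t = _table({0: np.array([2.0, 3.0]), 1: np.array([2.0, 3.0])})
        s = olr_sem_table(t)
        assert (s["sem"] == 0).all()

    def test_sem_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(6)
        sems = []
        for n in (4, 16):
            t = _table({m: 5 + rng.normal(size=3) for m in range(n)})
            sems.append(olr_sem_table(t)["sem"].mean())
        assert sems[0] / sems[1] == pytest.approx(2.0, rel=0.35)

    def test_gain_nan_at_zero_speed(self):
        t = _table({0: np.array([0.0, 2.0]), 1: np.array([0.0, 3.0])}, speeds=[0.0, 9.0])
        s = olr_sem_table(t)
        assert np.isnan(s.loc[s["speed"] == 0, "gain_mean"]).all()


class TestTTest:
    def test_all_zero_not_significant(self):
        p, sig, degen = ttest_vs_zero(np.zeros(6))
        assert p == 1.0 and not sig and degen

    def test_clearly_nonzero_significant(self):
        p, sig, degen = ttest_vs_zero(np.array([10.1, 9.9, 10.0, 10.2, 9.8, 10.0]))
        assert sig and p < 1e-6 and not degen

    def test_symmetric_values_give_p_one(self):
        p, sig, _ = ttest_vs_zero(np.array([-0.3, 0.3]))
        assert p == pytest.approx(1.0) and not sig

    def test_single_value_rejected(self):
        with pytest.raises(DataError):
            ttest_vs_zero(np.array([1.0]))


class TestMeanTraces:
    def test_aligned_shape_and_plateau(self, quiet_cohort, tuning):
        dataset, truth = quiet_cohort
        idx, traces = mean_condition_traces(dataset)
        assert traces.shape == (len(idx), 240)
        sel = (idx["mouse"] == 0) & (idx["speed"] == 54.0) & (idx["direction"] == "right")
        row = traces[sel.to_numpy()][0]
        g0 = truth["mice"][0]["gain_multiplier"]
        assert row[120:180].mean() == pytest.approx(g0 * tuning(54.0), rel=5e-3)
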