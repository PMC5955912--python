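"""Weighted polynomial fits, nested F-tests, peak finding, bootstrap peaks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from olrkit.exceptions import ArgumentError
from olrkit.fitting import (
    PeakEstimate,
    WeightedPolynomial,
    WeightedPolySurface,
    bootstrap_peak,
    fit_poly_weighted,
    fit_surface_weighted,
    nested_f_test,
    select_model,
    surface_terms,
)


def wls_normal_equations(X, y, se):
    """Independent oracle: solve the weighted normal equations directly."""
    w = 1.0 / np.asarray(se)
    A = X * w[:, None]
    b = y * w
    return np.linalg.solve(A.T @ A, A.T @ b)


class TestWeightedFit:
    def test_exact_parabola_recovered_any_weights(self):
        x = np.arange(9.0, 73.0, 9.0)
        y = 1.2 + 2.0 * x - 0.017 * x**2
        se = np.geomspace(0.1, 5.0, x.size)
        res = fit_poly_weighted(x, y, se, 2)
        np.testing.assert_allclose(res.params, [1.2, 2.0, -0.017], rtol=1e-10)
        assert res.rss == pytest.approx(0.0, abs=1e-14)
        assert res.rsquared == pytest.approx(1.0)

    def test_equal_weights_match_simple_linear_regression(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 12)
        y = 3 + 0.5 * x + rng.normal(0, 0.3, x.size)
        res = fit_poly_weighted(x, y, np.ones_like(x), 1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        np.testing.assert_allclose(res.params, [y.mean() - slope * x.mean(), slope], rtol=1e-10)

    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_matches_normal_equation_oracle_1d(self, degree):
        rng = np.random.default_rng(degree)
        for _ in range(20):
            x = rng.uniform(0, 80, 12)
            y = rng.normal(0, 10, 12)
            se = rng.uniform(0.2, 3.0, 12)
            res = fit_poly_weighted(x, y, se, degree)
            X = np.vander(x, degree + 1, increasing=True)
            np.testing.assert_allclose(res.params, wls_normal_equations(X, y, se), rtol=1e-8)
            r = y - X @ res.params
            assert res.rss == pytest.approx(float(np.sum((r / se) ** 2)), rel=1e-10)

    @pytest.mark.parametrize("order", [(2, 2), (2, 3), (3, 2)])
    def test_matches_normal_equation_oracle_surface(self, order):
        rng = np.random.default_rng(order[0] * 10 + order[1])
        n = 20
        x1 = np.tile(np.linspace(0.1, 1.0, 5), 4)
        x2 = np.repeat(np.linspace(18, 72, 4), 5)
        y = rng.normal(0, 5, n)
        se = rng.uniform(0.2, 2.0, n)
        res = fit_surface_weighted(x1, x2, y, se, order)
        X = np.column_stack([x1**i * x2**j for i, j in surface_terms(order)])
        np.testing.assert_allclose(res.params, wls_normal_equations(X, y, se), rtol=1e-8)

    def test_upweighted_point_residual_shrinks_monotonically(self):
        x = np.linspace(0, 10, 8)
        y = x**2 - 3 * x + np.array([0, 0, 0, 5.0, 0, 0, 0, 0])
        residuals = []
        for w in (1.0, 10.0, 1000.0):
            se = np.ones_like(x)
            se[3] = 1.0 / w
            res = fit_poly_weighted(x, y, se, 2)
            residuals.append(abs(y[3] - res.predict(x[3])))
        assert residuals[0] > residuals[1] > residuals[2]
        assert residuals[2] < 0.01

    def test_singular_design_rejected(self):
        x = np.full(6, 2.0)
        with pytest.raises(ArgumentError):
            fit_poly_weighted(x, np.arange(6.0), np.ones(6), 2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ArgumentError):
            fit_poly_weighted(np.arange(3.0), np.arange(3.0), np.ones(3), 2)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ArgumentError):
            fit_poly_weighted(np.arange(5.0), np.arange(5.0), np.zeros(5), 1)


class TestSurfaceTerms:
    def test_printed_parameter_counts(self):
        assert {o: len(surface_terms(o)) for o in [(2, 2), (2, 3), (3, 2), (3, 3)]} == {
            (2, 2): 6,
            (2, 3): 9,
            (3, 2): 9,
            (3, 3): 10,
        }

    def test_exponent_rule(self):
        for i, j in surface_terms((2, 3)):
            assert i <= 2 and j <= 3 and i + j <= 3

    def test_nested_surface_rss_not_larger(self):
        rng = np.random.default_rng(7)
        x1 = np.tile(np.linspace(0.1, 1.0, 5), 4)
        x2 = np.repeat(np.linspace(18, 72, 4), 5)
        beta = rng.normal(size=6)
        X22 = np.column_stack([x1**i * x2**j for i, j in surface_terms((2, 2))])
        y = X22 @ beta + rng.normal(0, 0.5, 20)
        se = np.ones(20)
        r22 = fit_surface_weighted(x1, x2, y, se, (2, 2))
        r23 = fit_surface_weighted(x1, x2, y, se, (2, 3))
        assert r23.rss <= r22.rss + 1e-10

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rss_monotone_under_nesting(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 80, 10)
        y = rng.normal(0, 5, 10)
        se = rng.uniform(0.5, 2.0, 10)
        rss = [fit_poly_weighted(x, y, se, d).rss for d in (1, 2, 3)]
        assert rss[0] >= rss[1] - 1e-9 >= rss[2] - 2e-9


class TestNestedFTest:
    def test_df_bookkeeping_8_points_line_vs_quadratic(self):
        rng = np.random.default_rng(8)
        x = np.arange(9.0, 73.0, 9.0)
        y = rng.normal(0, 1, 8)
        se = np.ones(8)
        ft = nested_f_test(fit_poly_weighted(x, y, se, 1), fit_poly_weighted(x, y, se, 2))
        assert (ft.df1, ft.df2) == (1, 5)

    def test_df_bookkeeping_20_points_poly22_vs_poly23(self):
        rng = np.random.default_rng(9)
        x1 = np.tile(np.linspace(0.1, 1.0, 5), 4)
        x2 = np.repeat(np.linspace(18, 72, 4), 5)
        y = rng.normal(0, 1, 20)
        se = np.ones(20)
        ft = nested_f_test(
            fit_surface_weighted(x1, x2, y, se, (2, 2)), fit_surface_weighted(x1, x2, y, se, (2, 3))
        )
        assert (ft.df1, ft.df2) == (3, 11)
        ft2 = nested_f_test(
            fit_surface_weighted(x1, x2, y, se, (2, 3)), fit_surface_weighted(x1, x2, y, se, (3, 3))
        )
        assert (ft2.df1, ft2.df2) == (1, 10)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(10)
        x1 = np.tile(np.linspace(0.1, 1.0, 5), 4)
        x2 = np.repeat(np.linspace(18, 72, 4), 5)
        y = rng.normal(0, 1, 20)
        se = np.ones(20)
        with pytest.raises(ArgumentError):
            nested_f_test(
                fit_surface_weighted(x1, x2, y, se, (2, 3)),
                fit_surface_weighted(x1, x2, y, se, (3, 2)),
            )

    def test_different_data_rejected(self):
        x = np.arange(8.0)
        se = np.ones(8)
        a = fit_poly_weighted(x, x**2, se, 1)
        b = fit_poly_weighted(x, x**2 + 1, se, 2)
        with pytest.raises(ArgumentError):
            nested_f_test(a, b)


class TestSelectModel:
    def test_zero_noise_linear_data_selects_line(self):
        x = np.arange(9.0, 73.0, 9.0)
        y = 2 + 0.5 * x
        se = np.ones(8)
        models = [WeightedPolynomial(y, x, se, degree=d) for d in (1, 2, 3)]
        res, trail = select_model(models)
        assert res.model.degree == 1
        assert trail[0].preferred == "small"

    def test_single_candidate_returned(self):
        x = np.arange(9.0, 73.0, 9.0)
        res, trail = select_model([WeightedPolynomial(x**2, x, np.ones(8), degree=2)])
        assert res.model.degree == 2 and trail == []

    def test_strong_quadratic_selected(self):
        x = np.arange(9.0, 73.0, 9.0)
        y = 35.0 * (1 - ((x - 57.2) / 57.2) ** 2)
        rng = np.random.default_rng(11)
        yn = y + rng.normal(0, 0.5, 8)
        models = [WeightedPolynomial(yn, x, np.full(8, 0.5), degree=d) for d in (1, 2, 3)]
        res, _ = select_model(models)
        assert res.model.degree == 2


class TestPeakFinding:
    def test_constructed_quadratic_peak(self):
        x = np.arange(9.0, 73.0, 9.0)
        y = 35.0 - ((x - 57.2) ** 2) / 100.0
        res = fit_poly_weighted(x, y, np.ones(8), 2)
        pk = res.peak((9.0, 72.0))
        assert pk.location[0] == pytest.approx(57.2, abs=1e-8)
        assert pk.height == pytest.approx(35.0, abs=1e-8)
        assert not pk.on_boundary and not pk.degenerate

    def test_upward_parabola_flagged_boundary_degenerate(self):
        x = np.arange(9.0, 73.0, 9.0)
        res = fit_poly_weighted(x, (x - 40.0) ** 2, np.ones(8), 2)
        pk = res.peak((9.0, 72.0))
        assert pk.on_boundary and pk.degenerate
        assert pk.location[0] in (9.0, 72.0)

    def test_random_surfaces_match_dense_grid_search(self):
        # brute-force oracle: 1000 x 1000 grid argmax
        rng = np.random.default_rng(12)
        dom = ((0.09, 0.95), (18.0, 72.0))
        for _ in range(10):
            x1 = np.tile(np.linspace(0.09, 0.95, 5), 4)
            x2 = np.repeat(np.linspace(18, 72, 4), 5)
            terms = surface_terms((2, 3))
            beta = rng.normal(0, 1, len(terms)) / [10.0 ** (i + 2 * j) for i, j in terms]
            X = np.column_stack([x1**i * x2**j for i, j in terms])
            res = fit_surface_weighted(x1, x2, X @ beta, np.ones(20), (2, 3))
            g1 = np.linspace(*dom[0], 1000)
            g2 = np.linspace(*dom[1], 1000)
            G1, G2 = np.meshgrid(g1, g2, indexing="ij")
            Z = res.predict(G1.ravel(), G2.ravel()).reshape(G1.shape)
            k = np.unravel_index(np.argmax(Z), Z.shape)
            pk = res.peak(dom)
            assert pk.height >= Z[k] - 1e-9
            assert abs(pk.location[0] - G1[k]) <= 2 * (g1[1] - g1[0]) + 1e-9
            assert abs(pk.location[1] - G2[k]) <= 2 * (g2[1] - g2[0]) + 1e-9


def _points_on_parabola(noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    speeds = np.arange(9.0, 73.0, 9.0)
    rows = []
    for mouse in range(6):
        for s in speeds:
            y = 35.0 * (1 - ((s - 57.2) / 57.2) ** 2) + rng.normal(0, noise_sd)
            rows.append({"mouse": mouse, "speed": s, "olr_norm": y})
    return pd.DataFrame(rows)


class TestBootstrapPeak:
    def test_noise_free_points_give_degenerate_distribution(self):
        pts = _points_on_parabola(noise_sd=1e-9, seed=1)
        est = bootstrap_peak(pts, 2, (9.0, 72.0), B=50, rng=2)
        assert est.mean_location[0] == pytest.approx(57.2, abs=1e-4)
        assert est.sd_location[0] < 1e-3
        assert est.mean_height == pytest.approx(35.0, abs=1e-4)

    def test_exactly_B_replicates_recorded(self):
        pts = _points_on_parabola(noise_sd=0.5, seed=3)
        est = bootstrap_peak(pts, 2, (9.0, 72.0), B=200, rng=4)
        assert est.n_boot == 200
        assert est.locations.shape == (200, 1)
        assert est.heights.shape == (200,)

    def test_covers_truth_at_moderate_noise(self):
        pts = _points_on_parabola(noise_sd=1.0, seed=5)
        est = bootstrap_peak(pts, 2, (9.0, 72.0), B=200, rng=6)
        assert est.covers([57.2])
        assert abs(est.mean_location[0] - 57.2) < 2 * max(est.sd_location[0], 0.5)

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ArgumentError):
            bootstrap_peak(_points_on_parabola(), 2, (9.0, 72.0), B=1, rng=0)

    def test_ellipse_matches_covariance_eigenstructure(self):
        rng = np.random.default_rng(13)
        cov = np.array([[4.0, 1.2], [1.2, 1.0]])
        pts = rng.multivariate_normal([40.0, 0.7], cov, size=4000)
        est = PeakEstimate(pts, np.zeros(4000))
        ell = est.ellipse(0.95)
        evals = np.sort(np.linalg.eigvalsh(np.cov(pts, rowvar=False)))[::-1]
        from scipy.stats import chi2

        np.testing.assert_allclose(ell["semi_axes"], np.sqrt(chi2.ppf(0.95, 2) * evals), rtol=1e-6)
        np.testing.assert_allclose(ell["center"], pts.mean(axis=0))
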