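"""Weighted polynomial tuning models, nested F-tests, bootstrap peak estimates.

Model objects follow the statsmodels convention: a model is constructed
from data and ``fit()`` returns a results object carrying estimates,
diagnostics and a ``summary()`` table.

* :class:`WeightedPolynomial` — 1-D polynomial of a single factor
  (typically stimulus speed), fitted by least squares with residuals
  weighted linearly by the inverse of the standard errors
  (minimize ``sum(((y - Xb)/se)**2)``).
* :class:`WeightedPolySurface` — 2-D polynomial ``polyMN`` of a factor
  and speed with term exponents ``i <= M``, ``j <= N``,
  ``i + j <= max(M, N)`` (so poly22 has 6 parameters, poly23/poly32
  have 9, poly33 has 10 — the MATLAB ``fit`` surface convention).
* :func:`nested_f_test` / :func:`select_model` — stepwise model-order
  selection via F-tests on weighted residual sums of squares.
* :func:`bootstrap_peak` — distribution of the fitted tuning peak over
  refits to resamples (with replacement) of the mouse x condition points,
  summarized by mean, SD, 95% percentile intervals and, for surfaces,
  the 95% normal-theory covariance ellipse of peak locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .exceptions import ArgumentError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "surface_terms",
    "WeightedPolynomial",
    "WeightedPolySurface",
    "PolynomialResults",
    "FTestResult",
    "PeakLocation",
    "PeakEstimate",
    "fit_poly_weighted",
    "fit_surface_weighted",
    "nested_f_test",
    "select_model",
    "peak_of_fit",
    "bootstrap_peak",
]


def surface_terms(order: tuple[int, int]) -> list[tuple[int, int]]:
    """Exponent pairs of a polyMN surface: i <= M, j <= N, i + j <= max(M, N)."""
    m, n = order
    if m < 0 or n < 0:
        raise ArgumentError("polynomial orders must be >= 0")
    cap = max(m, n)
    return [(i, j) for i in range(m + 1) for j in range(n + 1) if i + j <= cap]


def _design_1d(x: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x, degree + 1, increasing=True)


def _design_2d(x1: np.ndarray, x2: np.ndarray, terms: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.column_stack([x1**i * x2**j for i, j in terms])


class _WeightedPolyBase:
    """Shared machinery of the 1-D and 2-D weighted polynomial models."""

    def __init__(self, endog: np.ndarray, se: np.ndarray | None):
        self.endog = np.asarray(endog, dtype=float)
        n = self.endog.size
        if se is None:
            se = np.ones(n)
        self.se = np.asarray(se, dtype=float)
        if self.se.shape != self.endog.shape:
            raise ArgumentError("se must match y in shape")
        if np.any(self.se <= 0):
            raise ArgumentError("all standard errors must be > 0")

    def _check(self, X: np.ndarray) -> None:
        n, p = X.shape
        if n <= p:
            raise ArgumentError(f"need more points ({n}) than parameters ({p})")
        if np.linalg.matrix_rank(X / self.se[:, None]) < p:
            raise ArgumentError("singular design matrix")

    def fit(self) -> "PolynomialResults":
        X = self.design()
        self._check(X)
        # statsmodels WLS weights multiply squared residuals: w = 1/se**2
        # minimizes sum(((y - Xb)/se)**2), i.e. residuals weighted by 1/se.
        res = sm.WLS(self.endog, X, weights=1.0 / self.se**2).fit()
        return PolynomialResults(self, res)

    def design(self) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class WeightedPolynomial(_WeightedPolyBase):
    """1-D polynomial of degree ``degree``, inverse-SE weighted least squares."""

    def __init__(self, endog, x, se=None, degree: int = 2):
        super().__init__(endog, se)
        self.x = np.asarray(x, dtype=float)
        if self.x.shape != self.endog.shape:
            raise ArgumentError("x must match y in shape")
        if degree < 0:
            raise ArgumentError("degree must be >= 0")
        self.degree = int(degree)
        self.terms = [(k,) for k in range(degree + 1)]

    @classmethod
    def from_summary(cls, summary: pd.DataFrame, degree: int = 2, value: str = "mean_olr", sem: str = "sem"):
        """Build from a condition-summary frame (columns ``speed``, mean, SEM)."""
        df = summary[summary["speed"] > 0]
        return cls(df[value].to_numpy(), df["speed"].to_numpy(), df[sem].to_numpy(), degree)

    def design(self) -> np.ndarray:
        return _design_1d(self.x, self.degree)

    def design_at(self, x) -> np.ndarray:
        return _design_1d(np.atleast_1d(np.asarray(x, dtype=float)), self.degree)


class WeightedPolySurface(_WeightedPolyBase):
    """polyMN surface of (factor, speed), inverse-SE weighted least squares."""

    def __init__(self, endog, x1, x2, se=None, order: tuple[int, int] = (2, 3)):
        super().__init__(endog, se)
        self.x1 = np.asarray(x1, dtype=float)
        self.x2 = np.asarray(x2, dtype=float)
        if self.x1.shape != self.endog.shape or self.x2.shape != self.endog.shape:
            raise ArgumentError("x1 and x2 must match y in shape")
        self.order = (int(order[0]), int(order[1]))
        self.terms = surface_terms(self.order)

    def design(self) -> np.ndarray:
        return _design_2d(self.x1, self.x2, self.terms)

    def design_at(self, x1, x2) -> np.ndarray:
        x1 = np.atleast_1d(np.asarray(x1, dtype=float))
        x2 = np.atleast_1d(np.asarray(x2, dtype=float))
        return _design_2d(x1, x2, self.terms)


@dataclass(frozen=True)
class FTestResult:
    """Nested-model F-test on weighted residual sums of squares."""

    fvalue: float
    df1: int
    df2: int
    pvalue: float
    preferred: str  # 'small' | 'large'

    def __str__(self) -> str:
        return f"F({self.df1},{self.df2}) = {self.fvalue:.4g}, p = {self.pvalue:.4g} -> {self.preferred}"


@dataclass(frozen=True)
class PeakLocation:
    """Maximizer of a fitted polynomial over the tested domain."""

    location: tuple[float, ...]  # (speed,) or (factor, speed)
    height: float
    on_boundary: bool
    degenerate: bool = False  # no interior maximum exists (e.g. convex quadratic)


class PolynomialResults:
    """Fit results: coefficients, weighted RSS and R^2, prediction, peaks.

    ``rss`` is the weighted residual sum of squares
    ``sum(((y - yhat)/se)**2)``; ``rsquared`` is ``1 - RSS_w/TSS_w`` with
    the weighted total sum of squares taken about the weighted mean.
    """

    def __init__(self, model: _WeightedPolyBase, wls_results):
        self.model = model
        self._wls = wls_results
        self.params = np.asarray(wls_results.params, dtype=float)
        self.rss = float(wls_results.ssr)
        self.rsquared = float(wls_results.rsquared)
        self.nobs = int(wls_results.nobs)
        self.n_params = int(self.params.size)
        self.df_resid = self.nobs - self.n_params
        self.bse = np.asarray(wls_results.bse, dtype=float)

    # -- prediction --------------------------------------------------------

    def predict(self, *xs) -> np.ndarray:
        X = self.model.design_at(*xs)
        out = X @ self.params
        return out if out.size > 1 else float(out[0])

    # -- inference ---------------------------------------------------------

    def compare_f_test(self, restricted: "PolynomialResults") -> FTestResult:
        """F-test of this (larger) model against a nested restricted model."""
        return nested_f_test(restricted, self)

    # -- peaks -------------------------------------------------------------

    def peak(self, domain) -> PeakLocation:
        return peak_of_fit(self, domain)

    # -- reporting ---------------------------------------------------------

    def term_names(self) -> list[str]:
        if isinstance(self.model, WeightedPolynomial):
            return [f"x^{k}" if k else "1" for (k,) in self.model.terms]
        names = []
        for i, j in self.model.terms:
            bits = [f"{p}^{e}" if e > 1 else p for p, e in (("f", i), ("s", j)) if e]
            names.append("*".join(bits) if bits else "1")
        return names

    def summary(self) -> str:
        kind = (
            f"poly{self.model.degree}"
            if isinstance(self.model, WeightedPolynomial)
            else f"poly{self.model.order[0]}{self.model.order[1]}"
        )
        lines = [
            f"Weighted polynomial fit ({kind})",
            f"  n = {self.nobs}, parameters = {self.n_params}, df_resid = {self.df_resid}",
            f"  weighted RSS = {self.rss:.6g}, weighted R^2 = {self.rsquared:.4f}",
            f"  {'term':>8s} {'coef':>12s} {'se':>12s}",
        ]
        for name, b, se in zip(self.term_names(), self.params, self.bse):
            lines.append(f"  {name:>8s} {b:>12.5g} {se:>12.5g}")
        return "\n".join(lines)


def fit_poly_weighted(x, y, se, degree: int) -> PolynomialResults:
    """Functional form of the 1-D weighted polynomial fit."""
    return WeightedPolynomial(y, x, se, degree).fit()


def fit_surface_weighted(x1, x2, y, se, order: tuple[int, int]) -> PolynomialResults:
    """Functional form of the polyMN surface fit."""
    return WeightedPolySurface(y, x1, x2, se, order).fit()


def _terms_of(res: PolynomialResults) -> set[tuple]:
    return set(res.model.terms)


def nested_f_test(small: PolynomialResults, large: PolynomialResults) -> FTestResult:
    """F-test comparing nested weighted fits on the same data and weights.

    ``F = ((RSS_s - RSS_l)/dp) / (RSS_l/(n - p_l))`` with weighted RSS;
    degrees of freedom reported as ``(dp, n - p_l)``.
    """
    if small.nobs != large.nobs or not np.allclose(small.model.endog, large.model.endog):
        raise ArgumentError("models must be fitted to the same data")
    if not np.allclose(small.model.se, large.model.se):
        raise ArgumentError("models must use the same weights")
    if not _terms_of(small) < _terms_of(large):
        raise ArgumentError("small model's terms must be a strict subset of the large model's")
    dp = large.n_params - small.n_params
    df2 = large.df_resid
    if df2 <= 0:
        raise ArgumentError("large model leaves no residual degrees of freedom")
    num = max(small.rss - large.rss, 0.0) / dp
    den = large.rss / df2
    f = num / den if den > 0 else np.inf
    p = float(stats.f.sf(f, dp, df2))
    return FTestResult(float(f), dp, df2, p, "large" if p < 0.05 else "small")


def select_model(
    models: Sequence[_WeightedPolyBase], alpha: float = 0.05
) -> tuple[PolynomialResults, list[FTestResult]]:
    """Stepwise-up selection over a nested ladder of candidate models.

    Starting from the first (smallest) candidate, the next model is
    accepted iff its F-test against the current model has ``p < alpha``;
    selection stops at the first rejection.  Returns the selected fit and
    the trail of tests performed.
    """
    if not models:
        raise ArgumentError("need at least one candidate model")
    current = models[0].fit()
    trail: list[FTestResult] = []
    for cand in models[1:]:
        larger = cand.fit()
        ft = nested_f_test(current, larger)
        trail.append(ft)
        if ft.pvalue < alpha:
            current = larger
        else:
            break
    return current, trail


# ---------------------------------------------------------------------------
# Peak finding


def _peak_1d(res: PolynomialResults, domain: tuple[float, float]) -> PeakLocation:
    lo, hi = float(domain[0]), float(domain[1])
    coeffs = res.params
    poly = np.polynomial.Polynomial(coeffs)
    cands = [lo, hi]
    if len(coeffs) > 1:
        roots = poly.deriv().roots()
        cands += [float(r.real) for r in roots if abs(r.imag) < 1e-10 and lo < r.real < hi]
    vals = [float(poly(c)) for c in cands]
    k = int(np.argmax(vals))
    loc, height = cands[k], vals[k]
    on_boundary = k < 2
    degenerate = False
    if res.model.degree == 2 and coeffs[-1] >= 0:
        degenerate = True  # convex (or flat) quadratic has no interior maximum
    return PeakLocation((loc,), height, on_boundary, degenerate)


def _peak_2d(res: PolynomialResults, domain) -> PeakLocation:
    (l1, h1), (l2, h2) = domain
    g1 = np.linspace(l1, h1, 121)
    g2 = np.linspace(l2, h2, 121)
    G1, G2 = np.meshgrid(g1, g2, indexing="ij")
    Z = res.predict(G1.ravel(), G2.ravel()).reshape(G1.shape)
    k = np.unravel_index(np.argmax(Z), Z.shape)
    x0 = np.array([G1[k], G2[k]])

    def neg(v):
        return -res.predict(v[0], v[1])

    opt = optimize.minimize(
        neg,
        x0,
        bounds=[(l1, h1), (l2, h2)],
        method="L-BFGS-B",
        options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
    )
    # keep whichever of seed and refinement is higher (refinement can stall
    # within its tolerance a hair below a very fine grid's maximum)
    if -float(opt.fun) >= float(Z[k]):
        loc, height = opt.x, -float(opt.fun)
    else:
        loc, height = x0, float(Z[k])
    tol1 = 1e-6 * (h1 - l1)
    tol2 = 1e-6 * (h2 - l2)
    on_boundary = bool(
        loc[0] - l1 < tol1 or h1 - loc[0] < tol1 or loc[1] - l2 < tol2 or h2 - loc[1] < tol2
    )
    return PeakLocation((float(loc[0]), float(loc[1])), height, on_boundary)


def peak_of_fit(res: PolynomialResults, domain) -> PeakLocation:
    """Maximizer of a fitted polynomial over the closed tested domain.

    1-D fits use the analytic critical points of the polynomial plus the
    interval endpoints; surfaces use a dense grid seed refined by bounded
    local optimization.  Maxima attained on the domain boundary are
    flagged ``on_boundary``; a quadratic with no interior maximum is
    additionally flagged ``degenerate``.
    """
    if isinstance(res.model, WeightedPolynomial):
        return _peak_1d(res, domain)
    return _peak_2d(res, domain)


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class PeakEstimate:
    """Bootstrap distribution of a tuning-curve/surface peak.

    ``locations`` has one row per bootstrap replicate (1 column for
    curves: speed; 2 for surfaces: factor, speed); ``heights`` the fitted
    maximum of each replicate.  ``sd_location`` is the bootstrap SD (the
    convention used to report peak uncertainty), ``ci_location`` the 2.5
    and 97.5 percentiles per axis.
    """

    locations: np.ndarray  # (B, ndim)
    heights: np.ndarray  # (B,)
    n_redraws: int = 0

    @property
    def n_boot(self) -> int:
        return int(self.heights.size)

    @property
    def ndim(self) -> int:
        return int(self.locations.shape[1])

    @property
    def mean_location(self) -> np.ndarray:
        return self.locations.mean(axis=0)

    @property
    def sd_location(self) -> np.ndarray:
        return self.locations.std(axis=0, ddof=1)

    @property
    def ci_location(self) -> np.ndarray:
        """(2, ndim): rows are the 2.5 and 97.5 percentiles."""
        return np.percentile(self.locations, [2.5, 97.5], axis=0)

    @property
    def mean_height(self) -> float:
        return float(self.heights.mean())

    @property
    def sd_height(self) -> float:
        return float(self.heights.std(ddof=1))

    @property
    def ci_height(self) -> np.ndarray:
        return np.percentile(self.heights, [2.5, 97.5])

    @property
    def cov_location(self) -> np.ndarray:
        return np.cov(self.locations, rowvar=False).reshape(self.ndim, self.ndim)

    def ellipse(self, conf: float = 0.95) -> dict:
        """95% normal-theory covariance ellipse of the 2-D peak locations.

        Returns center, semi-axis lengths (scaled by ``sqrt(chi2_2(conf))``)
        and the rotation angle (radians) of the major axis.
        """
        if self.ndim != 2:
            raise DataError("ellipse is defined for 2-D peak locations only")
        cov = self.cov_location
        evals, evecs = np.linalg.eigh(cov)
        scale = np.sqrt(stats.chi2.ppf(conf, df=2))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        return {
            "center": self.mean_location,
            "semi_axes": scale * np.sqrt(np.maximum(evals, 0.0)),
            "angle": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
            "cov": cov,
        }

    def covers(self, truth: Sequence[float]) -> bool:
        """Whether ``truth`` lies inside the per-axis 95% percentile intervals."""
        ci = self.ci_location
        t = np.atleast_1d(np.asarray(truth, dtype=float))
        return bool(np.all((ci[0] <= t) & (t <= ci[1])))

    def summary(self) -> str:
        axes = ["factor", "speed"][-self.ndim :]
        lines = [f"Bootstrap peak estimate ({self.n_boot} replicates, {self.n_redraws} redraws)"]
        ci = self.ci_location
        for a, name in enumerate(axes):
            lines.append(
                f"  {name}: mean {self.mean_location[a]:.4g} (SD {self.sd_location[a]:.3g}), "
                f"95% CI [{ci[0, a]:.4g}, {ci[1, a]:.4g}]"
            )
        hci = self.ci_height
        lines.append(
            f"  height: mean {self.mean_height:.4g} (SD {self.sd_height:.3g}), "
            f"95% CI [{hci[0]:.4g}, {hci[1]:.4g}]"
        )
        return "\n".join(lines)


def bootstrap_peak(
    points: pd.DataFrame,
    order,
    domain,
    value: str = "olr_norm",
    factor: str | None = None,
    B: int = 200,
    rng: np.random.Generator | int | None = None,
    max_redraw: int | None = None,
) -> PeakEstimate:
    """Bootstrap the fitted tuning peak from mouse x condition points.

    ``points`` holds one row per mouse x condition (columns ``mouse``,
    ``speed``, the optional ``factor`` column, and ``value``).  Each of
    the ``B`` replicates resamples the rows with replacement, recomputes
    condition means and SEMs, refits the weighted polynomial (1-D of
    degree ``order`` when ``factor`` is None, else a polyMN surface of
    order ``order``) and records its peak.  Resamples in which a
    condition is absent, singly represented, or has zero SEM are redrawn
    (counted in ``n_redraws``).
    """
    if B < 2:
        raise ArgumentError("B must be >= 2")
    if max_redraw is None:
        # small cohorts degenerate often (e.g. 3 points per condition fail
        # the >=2-per-condition rule in most resamples); scale the cap with B
        max_redraw = max(10_000, 500 * B)
    gen = np.random.default_rng(rng)
    cond_cols = ["speed"] if factor is None else [factor, "speed"]
    pts = points[points["speed"] > 0].reset_index(drop=True)
    n = len(pts)
    n_cond = pts.groupby(cond_cols).ngroups
    y_all = pts[value].to_numpy()
    cond_arr = pts[cond_cols].to_numpy()
    # integer condition codes for fast per-replicate aggregation
    uniq, codes = np.unique(cond_arr, axis=0, return_inverse=True)

    locs: list[np.ndarray] = []
    heights: list[float] = []
    redraws = 0
    scale_floor = 1e-12 * max(1.0, float(np.abs(y_all).max()))
    while len(heights) < B:
        idx = gen.integers(0, n, size=n)
        c = codes[idx]
        counts = np.bincount(c, minlength=n_cond)
        if np.any(counts < 2):
            redraws += 1
            if redraws > max_redraw:
                raise DataError("too many degenerate bootstrap resamples")
            continue
        y = y_all[idx]
        means = np.empty(n_cond)
        sem = np.empty(n_cond)
        for k in range(n_cond):
            yk = y[c == k]
            means[k] = yk.mean()
            sem[k] = yk.std(ddof=1) / np.sqrt(yk.size)
        if np.all(sem <= scale_floor):
            sem = np.ones(n_cond)  # noise-free data: unweighted refit
        elif np.any(sem <= scale_floor):
            redraws += 1
            if redraws > max_redraw:
                raise DataError("too many degenerate bootstrap resamples")
            continue
        if factor is None:
            res = WeightedPolynomial(means, uniq[:, 0], sem, degree=int(order)).fit()
        else:
            res = WeightedPolySurface(means, uniq[:, 0], uniq[:, 1], sem, order=order).fit()
        pk = res.peak(domain)
        locs.append(np.asarray(pk.location))
        heights.append(pk.height)
    if redraws:
        logger.info("bootstrap_peak: redrew %d degenerate resamples", redraws)
    return PeakEstimate(np.vstack(locs), np.asarray(heights), n_redraws=redraws)
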