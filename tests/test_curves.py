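"""Lag reduction, minimum-risk reference, regional pooling."""

import numpy as np
import pytest

from heatsurge.basis import CrossBasisSpec
from heatsurge.curves import (
    ExposureResponse,
    find_reference,
    pool_region,
    pooled_curve,
    reduce_to_curve,
)
from heatsurge.models import FitResult


@pytest.fixture(scope="module")
def spec():
    return CrossBasisSpec(var_knots=(10.0, 20.0, 25.0), var_boundary=(-6.0, 45.0))


def synthetic_fit(spec, beta_cb, vcov_scale=1e-4, seed=0):
    """FitResult carrying only a crossbasis block."""
    k = spec.v_x * spec.v_l
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(k, k))
    vcov = vcov_scale * (A @ A.T + k * np.eye(k))
    return FitResult(
        beta=np.asarray(beta_cb, dtype=float),
        vcov=vcov,
        dispersion=1.0,
        column_map={"crossbasis": list(range(k))},
        names=[f"cb_{i}" for i in range(k)],
        n_obs=1000,
    )


class TestReduce:
    def test_zero_coefficients_flat_curve(self, spec):
        fit = synthetic_fit(spec, np.zeros(spec.v_x * spec.v_l))
        curve = reduce_to_curve(fit, spec, np.arange(-5.0, 40.0))
        assert np.abs(curve.log_rr).max() == 0.0
        assert np.all(curve.se >= 0)

    def test_matches_triple_sum_oracle(self, spec):
        rng = np.random.default_rng(4)
        beta = rng.normal(scale=0.05, size=spec.v_x * spec.v_l)
        fit = synthetic_fit(spec, beta)
        grid = np.linspace(-5, 40, 10)
        curve = reduce_to_curve(fit, spec, grid)
        bvar, blag = spec.var_basis, spec.lag_basis
        Bl = blag(np.arange(spec.max_lag + 1))
        for g, T in enumerate(grid):
            Bv = bvar([T])[0]
            total = sum(
                beta[i * spec.v_l + j] * Bv[i] * Bl[lag, j]
                for lag in range(spec.max_lag + 1)
                for i in range(spec.v_x)
                for j in range(spec.v_l)
            )
            assert abs(curve.log_rr[g] - total) < 1e-10

    def test_linearity_in_coefficients(self, spec):
        rng = np.random.default_rng(5)
        beta = rng.normal(scale=0.05, size=spec.v_x * spec.v_l)
        grid = np.arange(0.0, 30.0)
        c1 = reduce_to_curve(synthetic_fit(spec, beta), spec, grid)
        c2 = reduce_to_curve(synthetic_fit(spec, 2 * beta), spec, grid)
        assert np.allclose(c2.log_rr, 2 * c1.log_rr)

    def test_missing_crossbasis_block_rejected(self, spec):
        fit = synthetic_fit(spec, np.zeros(spec.v_x * spec.v_l))
        fit.column_map = {"other": fit.column_map["crossbasis"]}
        with pytest.raises(ValueError):
            reduce_to_curve(fit, spec, np.arange(5.0))


class TestReference:
    def grid_curve(self, spec, reduced_coef):
        grid = np.arange(-5.0, 40.0)
        B = spec.var_basis(grid)
        return ExposureResponse(
            temp_grid=grid,
            log_rr=B @ reduced_coef,
            se=np.zeros(grid.size),
            reduced_coef=np.asarray(reduced_coef),
            reduced_vcov=1e-4 * np.eye(spec.v_x),
        )

    def fit_coef_to_shape(self, spec, f):
        grid = np.arange(-5.0, 40.0)
        B = spec.var_basis(grid)
        return np.linalg.lstsq(B, f(grid), rcond=None)[0]

    def test_monotone_curve_refs_coldest_observed(self, spec):
        coef = self.fit_coef_to_shape(spec, lambda g: 0.004 * g)
        curve = self.grid_curve(spec, coef)
        observed = np.linspace(0, 35, 1000)
        centred = find_reference(curve, spec, observed)
        # coldest grid point within the central observed band
        assert centred.ref_temp <= np.percentile(observed, 1) + 1.0

    def test_u_shape_refs_nadir(self, spec):
        coef = self.fit_coef_to_shape(spec, lambda g: 0.001 * (g - 20.0) ** 2)
        curve = self.grid_curve(spec, coef)
        centred = find_reference(curve, spec, np.linspace(-5, 40, 2000))
        assert centred.ref_temp == pytest.approx(20.0, abs=1.5)

    def test_recentred_value_exactly_zero(self, spec):
        rng = np.random.default_rng(6)
        curve = self.grid_curve(spec, rng.normal(scale=0.05, size=spec.v_x))
        centred = find_reference(curve, spec, np.linspace(-5, 40, 500))
        at_ref = centred.log_rr[np.flatnonzero(centred.temp_grid == centred.ref_temp)[0]]
        assert at_ref == 0.0
        assert centred.se[np.flatnonzero(centred.temp_grid == centred.ref_temp)[0]] == 0.0

    def test_extrapolated_tails_not_eligible(self, spec):
        # steeply decreasing curve: unrestricted argmin would be the hottest
        # grid point, but observed data end at 25 degC
        coef = self.fit_coef_to_shape(spec, lambda g: -0.01 * g)
        curve = self.grid_curve(spec, coef)
        centred = find_reference(curve, spec, np.linspace(0, 25, 500))
        assert centred.ref_temp <= 25.0


class TestPooling:
    def test_single_county_identity(self):
        theta = np.array([0.1, -0.2, 0.3])
        V = np.diag([1.0, 2.0, 3.0])
        coef, vcov = pool_region([(theta, V)])
        assert np.allclose(coef, theta)
        assert np.allclose(vcov, V)

    def test_equal_inputs_halve_variance(self):
        theta = np.array([0.5, -0.1])
        V = np.array([[2.0, 0.3], [0.3, 1.0]])
        coef, vcov = pool_region([(theta, V), (theta, V)])
        assert np.allclose(coef, theta)
        assert np.allclose(vcov, V / 2)

    def test_three_counties_match_matrix_oracle(self):
        rng = np.random.default_rng(7)
        items = []
        for _ in range(3):
            A = rng.normal(size=(4, 4))
            items.append((rng.normal(size=4), A @ A.T + 4 * np.eye(4)))
        coef, vcov = pool_region(items)
        precision = sum(np.linalg.inv(V) for _, V in items)
        expect_v = np.linalg.inv(precision)
        expect_c = expect_v @ sum(np.linalg.inv(V) @ t for t, V in items)
        assert np.abs(coef - expect_c).max() < 1e-10
        assert np.abs(vcov - expect_v).max() < 1e-10

    def test_pooled_curve_in_convex_hull_for_equal_variances(self, spec):
        rng = np.random.default_rng(8)
        V = 1e-4 * np.eye(spec.v_x)
        thetas = [rng.normal(scale=0.05, size=spec.v_x) for _ in range(3)]
        grid = np.arange(0.0, 30.0)
        B = spec.var_basis(grid)
        pooled = pooled_curve([(t, V) for t in thetas], spec, grid)
        county_vals = np.stack([B @ t for t in thetas])
        assert np.all(pooled.log_rr >= county_vals.min(axis=0) - 1e-12)
        assert np.all(pooled.log_rr <= county_vals.max(axis=0) + 1e-12)

    def test_singular_vcov_ridge_stabilized(self):
        theta = np.array([0.1, 0.2])
        V = np.zeros((2, 2))
        with pytest.warns(UserWarning, match="ridge"):
            coef, _ = pool_region([(theta, V)])
        assert np.allclose(coef, theta, atol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_region([])


class TestNullTruthFlatness:
    def test_pooled_curve_flat_when_truth_has_no_effect(self):
        """Flat simulation truth: the pooled cumulative RR across five
        counties stays within [0.95, 1.05] over the observed range."""
        from heatsurge.models import adjust_counts, build_design, fit_quasipoisson
        from heatsurge.synthetic import SimConfig, TrueExposureResponse, gen_panel
        from heatsurge.basis import build_crossbasis

        g = np.arange(-15.0, 41.0)
        w = 0.6 ** np.arange(6)
        null = TrueExposureResponse(g, np.zeros_like(g), w / w.sum())
        cfg = SimConfig(n_counties=5, n_years=3, base_rate=50.0, seed=7)
        items, all_temps, spec = [], [], None
        for i in range(5):
            panel = adjust_counts(gen_panel(cfg, i, null))
            all_temps.append(panel.tmax)
            if spec is None:
                spec = CrossBasisSpec.from_temperatures(panel.tmax)
            cb = build_crossbasis(panel.tmax, spec)
            fit = fit_quasipoisson(build_design(panel, cb))
            c = reduce_to_curve(fit, spec, np.array([0.0]))
            items.append((c.reduced_coef, c.reduced_vcov))
        all_temps = np.concatenate(all_temps)
        lo, hi = np.percentile(all_temps, [1, 99])
        grid = np.arange(np.ceil(lo), np.floor(hi) + 0.5)
        pooled = pooled_curve(items, spec, grid, observed_temps=all_temps)
        rr = np.exp(pooled.log_rr)
        assert 0.95 <= rr.min() and rr.max() <= 1.05


class TestEndToEndCurve:
    def test_fitted_curve_linear_beyond_observed_range(self, fitted_county):
        panel, spec, cb, design, fit = fitted_county
        hi = spec.var_boundary[1]
        grid = np.array([hi + 1, hi + 3, hi + 5, hi + 7])
        curve = reduce_to_curve(fit, spec, grid)
        assert np.abs(np.diff(curve.log_rr, 2)).max() < 1e-9

    def test_rr_frame_wald_intervals(self, fitted_county):
        panel, spec, cb, design, fit = fitted_county
        curve = find_reference(
            reduce_to_curve(fit, spec, np.arange(0.0, 30.0)), spec, panel.tmax
        )
        df = curve.rr_frame()
        assert (df["rr_lo"] <= df["rr"]).all() and (df["rr"] <= df["rr_hi"]).all()
        assert np.allclose(df["rr"], np.exp(df["log_rr"]))
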