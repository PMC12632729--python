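"""County panel preparation and quasi-Poisson fitting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from heatsurge.basis import DataValidationError, build_crossbasis
from heatsurge.models import (
    CountyPanel,
    Design,
    adjust_counts,
    build_design,
    filter_counties,
    fit_quasipoisson,
)
from heatsurge.synthetic import SimConfig, gen_panel


def make_panel(enrollees_by_year, n_years=2, county="X"):
    dates = pd.date_range("2010-01-01", periods=365 * n_years + 1, freq="D")
    dates = dates[dates.year < 2010 + n_years]
    rng = np.random.default_rng(0)
    years = dates.year
    df = pd.DataFrame(
        {
            "date": dates,
            "tmax_c": 15 + 10 * np.sin(np.arange(len(dates)) / 58.0),
            "ed_visits": rng.poisson(20.0, len(dates)),
            "enrollees": [enrollees_by_year[int(y)] for y in years],
        }
    )
    return CountyPanel(county=county, region="Midwest", data=df)


class TestFilter:
    def test_501_every_year_retained(self):
        p = make_panel({2010: 501, 2011: 501})
        assert filter_counties([p]) == [p]

    def test_500_in_one_year_dropped(self):
        p = make_panel({2010: 501, 2011: 500})
        assert filter_counties([p]) == []

    def test_empty_input(self):
        assert filter_counties([]) == []


class TestAdjust:
    def test_constant_enrollment_identity(self):
        p = adjust_counts(make_panel({2010: 800, 2011: 800}))
        assert np.allclose(p.data["ed_adjusted"], p.data["ed_visits"])

    def test_half_enrollment_doubles_counts(self):
        p = make_panel({2010: 1000, 2011: 500})
        adj = adjust_counts(p)
        ref = 750.0
        y2010 = adj.dates.dt.year == 2010
        assert np.allclose(
            adj.data.loc[y2010.values, "ed_adjusted"],
            p.data.loc[y2010.values, "ed_visits"] * ref / 1000,
        )
        assert np.allclose(
            adj.data.loc[~y2010.values, "ed_adjusted"],
            p.data.loc[~y2010.values, "ed_visits"] * ref / 500,
        )

    def test_zero_enrollment_rejected(self):
        df = make_panel({2010: 800, 2011: 800}).data.copy()
        df["enrollees"] = 0
        with pytest.raises(DataValidationError):
            adjust_counts(CountyPanel("X", "Midwest", df))

    def test_offset_mode_keeps_counts(self):
        adj = adjust_counts(make_panel({2010: 1000, 2011: 500}), mode="offset")
        assert "offset" in adj.data.columns
        assert np.array_equal(adj.data["ed_visits"], adj.data["ed_visits"])


class TestPanelValidation:
    def test_date_gap_detected(self):
        p = make_panel({2010: 800, 2011: 800})
        df = p.data.drop(index=40).reset_index(drop=True)
        with pytest.raises(DataValidationError, match="gap"):
            CountyPanel("X", "Midwest", df)

    def test_negative_counts_rejected(self):
        df = make_panel({2010: 800, 2011: 800}).data.copy()
        df.loc[3, "ed_visits"] = -1
        with pytest.raises(DataValidationError):
            CountyPanel("X", "Midwest", df)


class TestDesign:
    def test_block_shapes(self, fitted_county):
        panel, spec, cb, design, _ = fitted_county
        assert len(design.column_map["dow"]) == 6
        assert len(design.column_map["time"]) == 8 * panel.n_years  # 24 for 3 years
        assert len(design.column_map["crossbasis"]) == spec.v_x * spec.v_l
        assert design.X.shape[0] == len(panel.data) - spec.max_lag

    def test_deterministic_after_row_permutation(self):
        cfg = SimConfig(n_years=1, seed=2)
        panel = gen_panel(cfg, 0)
        shuffled = panel.data.sample(frac=1.0, random_state=1).sort_values("date")
        panel2 = CountyPanel(panel.county, panel.region, shuffled.reset_index(drop=True))
        from heatsurge.basis import CrossBasisSpec

        spec = CrossBasisSpec.from_temperatures(panel.tmax)
        d1 = build_design(panel, build_crossbasis(panel.tmax, spec))
        d2 = build_design(panel2, build_crossbasis(panel2.tmax, spec))
        assert np.array_equal(d1.X, d2.X)


def toy_design(n=2000, seed=12):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.uniform(-1, 1, n)])
    beta = np.array([1.2, 0.3, -0.2])
    y = rng.poisson(np.exp(X @ beta))
    return Design(
        X=X, y=y.astype(float),
        column_map={"intercept": [0], "covars": [1, 2]},
        names=["intercept", "x1", "x2"], row_index=np.arange(n),
    ), beta


class TestQuasiPoisson:
    def test_poisson_data_dispersion_near_one(self):
        design, _ = toy_design()
        fit = fit_quasipoisson(design)
        assert 0.9 <= fit.dispersion <= 1.1

    def test_se_is_sqrt_phi_times_poisson_se(self):
        design, _ = toy_design()
        fit = fit_quasipoisson(design)
        res_pois = sm.GLM(design.y, design.X, family=sm.families.Poisson()).fit(
            scale=1.0, maxiter=100, tol=1e-8
        )
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.vcov)),
            np.sqrt(fit.dispersion) * res_pois.bse,
            rtol=1e-6,
        )

    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(7.0, 500).astype(float)
        design = Design(
            X=np.ones((500, 1)), y=y, column_map={"intercept": [0]},
            names=["intercept"], row_index=np.arange(500),
        )
        fit = fit_quasipoisson(design)
        assert np.exp(fit.beta[0]) == pytest.approx(y.mean(), rel=1e-8)

    def test_negative_response_rejected(self):
        design, _ = toy_design(n=50)
        design.y[0] = -1
        with pytest.raises(DataValidationError):
            fit_quasipoisson(design)

    def test_vcov_symmetric_psd(self, fitted_county):
        *_, fit = fitted_county
        assert np.allclose(fit.vcov, fit.vcov.T)
        assert np.linalg.eigvalsh(fit.vcov).min() > -1e-10

    def test_fit_result_json_round_trip(self, fitted_county):
        from heatsurge.models import FitResult

        *_, fit = fitted_county
        back = FitResult.from_json(fit.to_json())
        assert np.allclose(back.beta, fit.beta)
        assert np.allclose(back.vcov, fit.vcov)
        assert back.column_map == fit.column_map


class TestNoSpuriousEffect:
    def test_null_crossbasis_deviance_gain_below_df_penalty(self):
        """On flat-truth simulations the crossbasis should absorb no more
        than its degrees of freedom on the quasi-deviance scale, on average."""
        from heatsurge.basis import CrossBasisSpec
        from heatsurge.synthetic import TrueExposureResponse

        g = np.arange(-15.0, 41.0)
        w = 0.6 ** np.arange(6)
        null = TrueExposureResponse(g, np.zeros_like(g), w / w.sum())
        gains, dfs = [], None
        cfg = SimConfig(n_counties=3, n_years=2, base_rate=50.0, seed=7)
        for i in range(3):
            panel = adjust_counts(gen_panel(cfg, i, null))
            spec = CrossBasisSpec.from_temperatures(panel.tmax)
            cb = build_crossbasis(panel.tmax, spec)
            design = build_design(panel, cb)
            full = fit_quasipoisson(design)
            idx = design.column_map["crossbasis"]
            keep = [j for j in range(design.X.shape[1]) if j not in idx]
            reduced = Design(
                X=design.X[:, keep], y=design.y,
                column_map={"rest": list(range(len(keep)))},
                names=[design.names[j] for j in keep], row_index=design.row_index,
            )
            null_fit = fit_quasipoisson(reduced)

            def dev(fit_, X):
                mu = np.exp(X @ fit_.beta)
                y = design.y
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = np.where(y > 0, y * np.log(y / mu), 0.0)
                return 2 * np.sum(term - (y - mu))

            gains.append((dev(null_fit, design.X[:, keep]) - dev(full, design.X)) / full.dispersion)
            dfs = len(idx)
        # quasi-deviance gain ~ chi2_df under the null; mean below 2x df penalty
        assert np.mean(gains) < 2 * dfs
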