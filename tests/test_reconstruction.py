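"""Predictor alignment, OLS fitting, model selection, the reliability gate
and split-sample verification of the reconstruction module."""

import numpy as np
import pandas as pd
import pytest

from alderhydro.chronology import SiteChronology
from alderhydro.examples import WORKED_EXAMPLE_MODELS
from alderhydro.reconstruction import (
    RWI_POOL,
    LinearReconModel,
    build_predictor_table,
    fit_ols,
    predict,
    reconstruction_window,
    select_best,
    verify,
)


def make_table(rng, n=40, slope=14.4390, intercept=60.0453, noise_sd=0.0, col="spei_24"):
    x = rng.standard_normal(n)
    y = slope * x + intercept + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({"target": y, col: x}, index=np.arange(1972, 1972 + n))


def make_chronology(depth, eps_vals, first_year=1900):
    n = len(depth)
    return SiteChronology(
        site_id="SYN",
        first_year=first_year,
        values=np.ones(n),
        sample_depth=np.asarray(depth, int),
        running_eps=np.asarray(eps_vals, float),
        method="horizontal_standardized",
    )


class TestFitOLS:
    def test_noiseless_planted_equation_recovered_exactly(self, rng):
        table = make_table(rng)
        model = fit_ols(table, ["spei_24"])
        assert model.coefficients["spei_24"] == pytest.approx(14.4390, abs=1e-6)
        assert model.intercept == pytest.approx(60.0453, abs=1e-6)
        assert model.r2 == pytest.approx(1.0, abs=1e-9)

    def test_null_target_explains_nothing(self, rng):
        table = pd.DataFrame(
            {"target": rng.standard_normal(10_000), "x": rng.standard_normal(10_000)},
            index=np.arange(10_000),
        )
        assert fit_ols(table, ["x"]).r2 < 0.001

    def test_planted_slope_recovered_within_ten_percent(self, rng):
        slopes = []
        for _ in range(200):
            table = make_table(rng, n=40, slope=30.0, intercept=0.0, noise_sd=24.5, col="x")
            slopes.append(fit_ols(table, ["x"]).coefficients["x"])
        assert np.mean(slopes) == pytest.approx(30.0, rel=0.10)

    def test_residuals_orthogonal_to_predictors(self, rng):
        table = make_table(rng, noise_sd=10.0)
        table["extra"] = rng.standard_normal(len(table))
        model = fit_ols(table, ["spei_24", "extra"])
        resid = table["target"] - predict(model, table)
        for p in ("spei_24", "extra"):
            assert abs(resid @ table[p]) < 1e-8

    def test_nested_models_never_lose_r2(self, rng):
        table = make_table(rng, noise_sd=20.0)
        table["rwi_t"] = rng.standard_normal(len(table))
        table["rwi_t1"] = rng.standard_normal(len(table))
        r2_small = fit_ols(table, ["rwi_t"]).r2
        r2_large = fit_ols(table, ["rwi_t", "rwi_t1"]).r2
        assert r2_large >= r2_small - 1e-12

    def test_collinear_predictors_rejected(self, rng):
        table = make_table(rng, col="a")
        table["b"] = 2.0 * table["a"]
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(table, ["a", "b"])


class TestSelectBest:
    def _model(self, predictors, r2):
        return LinearReconModel(
            "target", tuple(predictors), 0.0, {p: 1.0 for p in predictors},
            (1972, 2011), r2, 0.01, 40,
        )

    def test_pool_of_one(self):
        m = self._model(["rwi_t"], 0.3)
        assert select_best([m]) is m

    def test_higher_r2_wins(self):
        a, b = self._model(["spei_24"], 0.7), self._model(["spei_72"], 0.5)
        assert select_best([a, b]) is a

    def test_tie_prefers_fewer_predictors_then_smaller_lag(self):
        single = self._model(["rwi_t"], 0.4)
        double = self._model(["rwi_t", "rwi_t1"], 0.4)
        assert select_best([double, single]) is single
        lag0, lag1 = self._model(["rwi_t"], 0.4), self._model(["rwi_t1"], 0.4)
        assert select_best([lag1, lag0]) is lag0

    def test_planted_scale_selected_from_noisy_pool(self, rng):
        # moderately noisy target driven by one predictor among correlated
        # alternatives: selection should find the true one most of the time
        hits = 0
        reps = 20
        for _ in range(reps):
            base = rng.standard_normal(40)
            table = pd.DataFrame(index=np.arange(1972, 2012), data={
                "spei_24": base,
                "spei_72": 0.6 * base + 0.8 * rng.standard_normal(40),
            })
            table["target"] = 10.0 * table["spei_24"] + 8.0 * rng.standard_normal(40)
            best = select_best([fit_ols(table, [c]) for c in ("spei_24", "spei_72")])
            hits += best.predictors == ("spei_24",)
        assert hits / reps >= 0.9


class TestPredictorTable:
    def _inputs(self, rng, chron_years=(1950, 2011)):
        years = np.arange(chron_years[0], chron_years[1] + 1)
        n = len(years)
        chron = SiteChronology(
            "SYN", chron_years[0], rng.lognormal(0, 0.1, n), np.full(n, 15),
            np.full(n, 0.9), "horizontal_standardized",
        )
        from alderhydro.climate_spei import WaterYearSeries

        target = WaterYearSeries(
            "SYN", "lake_level",
            pd.DataFrame({
                "water_year": years, "value": rng.normal(60, 5, n),
                "n_months": 12, "complete": True,
            }),
        )
        spei_wy = {
            24: WaterYearSeries(
                "SYN", "spei_24",
                pd.DataFrame({
                    "water_year": years, "value": rng.standard_normal(n),
                    "n_months": 12, "complete": True,
                }),
            )
        }
        return chron, spei_wy, target

    def test_lag_alignment(self, rng):
        chron, spei_wy, target = self._inputs(rng)
        table = build_predictor_table(chron, spei_wy, target)
        chron_s = chron.to_series()
        assert table.loc[2000, "rwi_t1"] == chron_s.loc[2001]
        assert table.loc[2000, "rwi_t"] == chron_s.loc[2000]

    def test_final_year_dropped_for_missing_lead(self, rng):
        chron, spei_wy, target = self._inputs(rng)
        table = build_predictor_table(chron, spei_wy, target)
        assert 2011 not in table.index  # rwi_{t+1} undefined for the last year
        assert 2010 in table.index

    def test_target_gap_removes_row(self, rng):
        chron, spei_wy, target = self._inputs(rng)
        target.data.loc[target.data["water_year"] == 1980, "complete"] = False
        table = build_predictor_table(chron, spei_wy, target)
        assert 1980 not in table.index

    def test_too_few_rows_rejected(self, rng):
        chron, spei_wy, target = self._inputs(rng, chron_years=(2000, 2011))
        with pytest.raises(ValueError, match="water years"):
            build_predictor_table(chron, spei_wy, target)


class TestReconstructionWindow:
    def test_full_span_when_gates_always_pass(self):
        w = reconstruction_window(make_chronology([12] * 50, [0.9] * 50))
        assert (w.first_year, w.last_year) == (1900, 1949)

    def test_interior_depth_dip_truncates_to_longest_run(self):
        depth = [12] * 50
        depth[30] = 9
        w = reconstruction_window(make_chronology(depth, [0.9] * 50))
        assert (w.first_year, w.last_year) == (1900, 1929)

    def test_low_eps_years_excluded(self):
        eps_vals = [0.9] * 50
        eps_vals[:20] = [0.5] * 20
        w = reconstruction_window(make_chronology([12] * 50, eps_vals))
        assert (w.first_year, w.last_year) == (1920, 1949)

    def test_no_qualifying_year_gives_none(self):
        assert reconstruction_window(make_chronology([5] * 30, [0.9] * 30)) is None

    def test_undefined_eps_margins_fail_gate(self):
        eps_vals = [np.nan] * 5 + [0.9] * 20 + [np.nan] * 5
        w = reconstruction_window(make_chronology([12] * 30, eps_vals))
        assert (w.first_year, w.last_year) == (1905, 1924)


class TestPredict:
    @pytest.mark.parametrize(
        "name,expected",
        [("tiefer_see_spei", 60.0453), ("fuerstensee_spei", 60.3187)],
    )
    def test_worked_example_intercepts_at_zero_predictor(self, name, expected):
        model = WORKED_EXAMPLE_MODELS[name]
        frame = pd.DataFrame({model.predictors[0]: [0.0]}, index=[2000])
        assert predict(model, frame).iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_zero_slope_model_is_constant(self):
        model = LinearReconModel(
            "lake_level", ("rwi_t",), 42.0, {"rwi_t": 0.0}, (1972, 2011), 0.0, 1.0, 40
        )
        frame = pd.DataFrame({"rwi_t": np.linspace(-3, 3, 25)}, index=np.arange(25))
        np.testing.assert_allclose(predict(model, frame), 42.0)

    def test_missing_predictor_years_become_gaps(self):
        model = WORKED_EXAMPLE_MODELS["tiefer_see_spei"]
        frame = pd.DataFrame({"spei_24": [0.0, np.nan, 1.0]}, index=[2000, 2001, 2002])
        out = predict(model, frame)
        assert np.isnan(out.loc[2001]) and np.isfinite(out.loc[2002])


class TestHeadlineContrast:
    def test_weak_rwi_coupling_but_strong_spei_skill_under_study_conditions(self):
        """Under the default study conditions (short gauge era, weakly
        hydro-coupled stands), tree-ring models explain little lake-level
        variance while single-scale SPEI models explain much more."""
        from alderhydro.pipeline import (
            RECON_SCALES,
            build_site_chronologies,
            reconstruct_site,
            spei_suite,
        )
        from alderhydro.synthetic_data import (
            SyntheticConfig,
            observed_gauge_record,
            simulate_site,
        )

        cfg = SyntheticConfig()
        rwi_r2, spei_r2 = [], []
        for site in range(cfg.n_sites):
            climate, lake, trees = simulate_site(cfg, site)
            gauge = observed_gauge_record(lake, cfg)
            chrons = build_site_chronologies(trees)
            spei_set = spei_suite(climate, cfg.latitude_deg, scales=RECON_SCALES)
            res = reconstruct_site(chrons.chron_standardized, spei_set, gauge)
            rwi_r2.append(res.best_rwi.r2)
            spei_r2.append(res.best_spei.r2)
        assert 0.05 <= np.mean(rwi_r2) <= 0.4
        for rwi, spei in zip(rwi_r2, spei_r2):
            assert spei > rwi + 0.2


class TestVerify:
    def test_noiseless_model_verifies_perfectly(self, rng):
        table = make_table(rng, n=40)
        model = fit_ols(table, ["spei_24"])
        stats = verify(model, table)
        assert stats["holdout_r2"] == pytest.approx(1.0, abs=1e-9)
        assert stats["reduction_of_error"] == pytest.approx(1.0, abs=1e-9)

    def test_null_target_fails_verification_on_average(self, rng):
        vals = []
        for _ in range(100):
            table = pd.DataFrame(
                {"target": rng.standard_normal(40), "x": rng.standard_normal(40)},
                index=np.arange(40),
            )
            model = fit_ols(table, ["x"])
            vals.append(verify(model, table)["holdout_r2"])
        assert np.mean(vals) <= 0.0

    def test_holdout_tracks_calibration_for_real_signal(self, rng):
        # planted R^2 ~ 0.6: holdout skill should sit near calibration skill
        gaps = []
        for _ in range(100):
            table = make_table(rng, n=60, slope=30.0, intercept=0.0, noise_sd=24.5, col="x")
            model = fit_ols(table, ["x"])
            stats = verify(model, table)
            gaps.append(stats["holdout_r2"] - stats["calibration_r2"])
        assert abs(np.mean(gaps)) < 0.15

    def test_small_holdout_skipped_with_warning(self, rng, caplog):
        table = make_table(rng, n=20)
        model = fit_ols(table, ["spei_24"])
        with caplog.at_level("WARNING"):
            assert verify(model, table, holdout_fraction=0.1) is None
        assert "holdout" in caplog.text
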