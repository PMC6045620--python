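"""Cross-validated model selection: oracles, leakage guards, recovery."""

import numpy as np
import pytest
from scipy import stats

from pyrocast._irls import irls_line, irls_slope
from pyrocast.firemodel import (
    BurnedAreaModel,
    candidate_accumulations,
    candidate_predictors,
    fit_two_predictor,
    loocv_predict,
    select_best_model,
    target_month,
)
from pyrocast.indicators import IndicatorSpec
from pyrocast.preprocess import SeasonSpec


class TestCandidates:
    def test_exactly_eighteen(self):
        cands = candidate_predictors()
        assert len(cands) == 18
        assert len({(c.t, c.lag) for c in cands}) == 18

    def test_ordered_for_tie_breaking(self):
        cands = candidate_predictors()
        keys = [(c.t, c.lag) for c in cands]
        assert keys == sorted(keys)

    def test_target_month_arithmetic(self):
        jja = SeasonSpec("JJA")
        assert [target_month(jja, lag) for lag in range(6)] == [8, 7, 6, 5, 4, 3]
        djf = SeasonSpec("DJF")
        # lag 5 from February reaches back to September of the prior year
        assert [target_month(djf, lag) for lag in range(6)] == [2, 1, 12, 11, 10, 9]


def _loo_fold_oracle(y, x, j):
    """Explicit single-fold computation: robust-detrend/standardize both
    series on the training years, robust slope-only fit, predict year j."""
    n = len(y)
    train = np.delete(np.arange(n), j)
    yrs = np.arange(n, dtype=float)

    def prep(series):
        a, b, _ = irls_line(yrs[train], series[train][None, :])
        resid = series[train] - (a[0] + b[0] * yrs[train])
        mu, sd = resid.mean(), resid.std(ddof=1)
        z_train = (resid - mu) / sd
        z_held = (series[j] - (a[0] + b[0] * yrs[j]) - mu) / sd
        return z_train, z_held

    zy, zy_held = prep(y)
    zx, zx_held = prep(x)
    beta, _ = irls_slope(zx[None, :], zy[None, :])
    return beta[0] * zx_held, zy_held, beta[0]


class TestLoocvPredict:
    def test_noiseless_perfect_model(self, rng):
        x = rng.normal(size=21)
        fit = loocv_predict(1.0 * x, x)
        np.testing.assert_allclose(fit.predictions, fit.observed, atol=1e-8)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.p_value < 1e-10
        np.testing.assert_allclose(fit.betas, 1.0, atol=1e-8)

    def test_matches_bruteforce_fold_oracle(self, rng):
        y = rng.normal(size=8)
        x = rng.normal(size=8)
        fit = loocv_predict(y, x)
        for j in range(8):
            pred, obs, beta = _loo_fold_oracle(y, x, j)
            assert fit.predictions[j] == pytest.approx(pred, abs=1e-10)
            assert fit.observed[j] == pytest.approx(obs, abs=1e-10)
            assert fit.betas[j] == pytest.approx(beta, abs=1e-10)

    def test_leakage_guard_heldout_value_does_not_move_own_prediction(self, rng):
        y = rng.normal(size=21)
        x = rng.normal(size=21)
        fit = loocv_predict(y, x)
        y2 = y.copy()
        y2[7] = 99.0
        fit2 = loocv_predict(y2, x)
        assert fit2.predictions[7] == pytest.approx(fit.predictions[7], abs=1e-12)

    def test_too_few_years_rejected(self, rng):
        with pytest.raises(ValueError, match="paired years"):
            loocv_predict(rng.normal(size=5), rng.normal(size=5))

    def test_reported_beta_is_mean_of_folds(self, rng):
        x = rng.normal(size=21)
        fit = loocv_predict(-0.7 * x + 0.1 * rng.normal(size=21), x)
        assert fit.beta == pytest.approx(np.nanmean(fit.betas))
        assert fit.beta < 0


class TestSelectBestModel:
    def test_all_noise_often_returns_none(self, rng):
        # not a rate test, just the contract: None is a valid outcome
        outcomes = []
        for _ in range(20):
            y = rng.normal(size=21)
            preds = {IndicatorSpec("spi", t, l): rng.gamma(2.0, 50.0, 21)
                     for t in (3, 6, 12) for l in range(6)}
            outcomes.append(select_best_model(y, preds))
        assert any(c is None for c in outcomes)

    def test_tie_break_prefers_small_t_then_small_lag(self, rng):
        x = rng.normal(size=21)
        y = 1.0 * x
        # two identical candidate series -> identical r; the (3, 0) wins
        preds = {
            IndicatorSpec("spi", 6, 2): x.copy(),
            IndicatorSpec("spi", 3, 0): x.copy(),
        }
        cell = select_best_model(y, preds, standardizer="linear")
        assert (cell.spec.t, cell.spec.lag) == (3, 0)

    def test_recovers_planted_candidate(self, rng):
        # plant a signal on candidate (6, 1) among noise candidates
        signal = rng.normal(size=21)
        y = -0.8 * signal + 0.3 * rng.normal(size=21)
        preds = {}
        for t in (3, 6, 12):
            for lag in range(6):
                preds[IndicatorSpec("spi", t, lag)] = (
                    signal.copy() if (t, lag) == (6, 1) else rng.normal(size=21)
                )
        cell = select_best_model(y, preds, standardizer="linear")
        assert cell is not None
        assert (cell.spec.t, cell.spec.lag) == (6, 1)
        assert cell.beta < 0

    def test_selected_max_mode_tests_only_the_maximum(self, rng):
        y = rng.normal(size=21)
        preds = {IndicatorSpec("spi", t, l): rng.normal(size=21)
                 for t in (3, 6, 12) for l in range(6)}
        a = select_best_model(y, preds, standardizer="linear", p_mode="per_candidate")
        b = select_best_model(y, preds, standardizer="linear", p_mode="selected_max")
        # when the overall max is significant both modes agree on the winner
        if a is not None and b is not None:
            assert (b.spec.t, b.spec.lag) == (a.spec.t, a.spec.lag)


class TestTwoPredictor:
    def test_gamma_recovered_near_zero_when_absent(self, rng):
        x = rng.normal(size=21)
        temp = rng.normal(size=21)
        y = -0.9 * x + 0.15 * rng.normal(size=21)
        preds = {IndicatorSpec("spi", 3, 0): x}
        tpreds = {IndicatorSpec("spi", 3, 0): temp}
        cell = fit_two_predictor(y, preds, tpreds, standardizer="linear")
        assert cell is not None
        assert abs(cell.fit.gamma) < 0.35
        assert cell.fit.beta == pytest.approx(-0.9, abs=0.3)

    def test_collinear_predictors_do_not_crash(self, rng):
        x = rng.normal(size=21)
        y = x + 0.1 * rng.normal(size=21)
        cell = fit_two_predictor(
            y, {IndicatorSpec("spi", 3, 0): x}, {IndicatorSpec("spi", 3, 0): x.copy()},
            standardizer="linear",
        )
        assert cell is None or np.isfinite(cell.r)

    def test_matches_normal_equations_when_weights_unity(self, rng):
        # tiny residuals keep every bisquare weight at ~1: the robust fit
        # equals the least-squares solution of the two-column design
        x = rng.normal(size=12)
        w = rng.normal(size=12)
        from pyrocast._irls import irls
        design = np.stack([x, w], axis=-1)[None]
        y = (0.4 * x - 0.25 * w + 1e-10 * rng.normal(size=12))[None, :]
        coef, conv = irls(design, y)
        lstsq = np.linalg.lstsq(design[0], y[0], rcond=None)[0]
        np.testing.assert_allclose(coef[0], lstsq, atol=1e-8)


class TestGridModel:
    def test_sign_consistency_on_synthetic_cells(self, small_pipeline):
        sc, precip, temp, ba, monthly = small_pipeline
        model = BurnedAreaModel(
            ba=monthly, precip=precip.values, season="JJA",
            months=precip["time"].dt.month.values,
            years=precip["time"].dt.year.values,
        )
        res = model.fit()
        assert np.all(res.beta[res.significant] < 0)

    def test_summary_mentions_key_fields(self, small_pipeline):
        sc, precip, temp, ba, monthly = small_pipeline
        model = BurnedAreaModel(
            ba=monthly, precip=precip.values, season="JJA",
            months=precip["time"].dt.month.values,
            years=precip["time"].dt.year.values,
        )
        res = model.fit()
        text = res.summary()
        for token in ("JJA", "burnable", "significant", "mean r"):
            assert token in text

    def test_candidate_accumulations_match_manual_windows(self, small_climate, jja):
        precip, _ = small_climate
        months = precip["time"].dt.month.values
        years = precip["time"].dt.year.values
        vals = precip.values
        sy = np.array([2000, 2001])
        acc = candidate_accumulations(vals, months, years, jja, sy)
        assert set(acc) == {(t, l) for t in (3, 6, 12) for l in range(6)}
        # (t=3, lag=1): JJA target July -> sum of May..July
        i = np.where((months == 7) & (years == 2000))[0][0]
        expect = vals[i - 2 : i + 1].sum(axis=0)
        np.testing.assert_allclose(acc[(3, 1)][0], expect, atol=1e-10)

    def test_indicator_validation(self, small_pipeline):
        sc, precip, temp, ba, monthly = small_pipeline
        with pytest.raises(ValueError, match="requires temperature"):
            BurnedAreaModel(
                ba=monthly, precip=precip.values, season="JJA",
                months=precip["time"].dt.month.values,
                years=precip["time"].dt.year.values,
                indicator="spei",
            )

    def test_spei_and_t_indicator_paths_run(self, small_pipeline):
        sc, precip, temp, ba, monthly = small_pipeline
        kwargs = dict(
            ba=monthly, precip=precip.values, season="JJA",
            months=precip["time"].dt.month.values,
            years=precip["time"].dt.year.values,
            temp=temp.values, latitudes=sc.latitudes(),
        )
        for ind in ("spei", "t", "spi+t"):
            res = BurnedAreaModel(indicator=ind, **kwargs).fit()
            assert res.eligible.any()
            if ind == "spi+t" and res.significant.any():
                assert np.isfinite(res.gamma[res.significant]).all()
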