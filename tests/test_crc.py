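"""Nonlinear CRC fitting, goodness of fit and the observation band."""

import numpy as np
import pytest

from toxmix import (
    CRCFitError,
    CRCRegressor,
    DegenerateDataError,
    datasets,
    fit_crc,
    fit_metrics,
    select_best_family,
)
from toxmix.families import get_family


def weibull(x, alpha, beta):
    return 1 - np.exp(-np.exp(alpha + beta * np.log10(x)))


class TestFitMetrics:
    def test_perfect_fit(self):
        y = [0.1, 0.4, 0.9]
        q = fit_metrics(y, y)
        assert (q.r2, q.mse, q.mae) == (1.0, 0.0, 0.0)

    def test_anticorrelated_binary_example(self):
        # hand computation: SSR = 2, SStot = 0.5 -> R2 = 1 - 4 = -3
        q = fit_metrics([0.0, 1.0], [1.0, 0.0])
        assert q.r2 == pytest.approx(-3.0)
        assert q.mse == pytest.approx(1.0)
        assert q.mae == pytest.approx(1.0)

    def test_reported_curve_against_reported_quality(self, cr96_data):
        # the reported Cr 96-h parameters reproduce the reported R2/MAE
        x, y = cr96_data
        q = fit_metrics(y, weibull(x, -0.4, 1.21))
        assert round(q.r2, 2) == 0.96
        assert round(q.mae, 2) == 0.05

    def test_constant_observed_rejected(self):
        with pytest.raises(DegenerateDataError, match="undefined"):
            fit_metrics([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            fit_metrics([0.1, 0.2], [0.1, 0.2, 0.3])


class TestFit:
    def test_reference_chromium_series_quality(self, cr96_weibull_fit):
        fit = cr96_weibull_fit
        assert fit.quality_.r2 >= 0.96
        assert fit.quality_.mae <= 0.05
        assert fit.alpha_ == pytest.approx(-0.4, abs=0.02)
        assert fit.beta_ == pytest.approx(1.21, abs=0.02)

    def test_noise_free_recovery(self):
        x = np.array([0.05, 0.2, 1.0, 3.0, 10.0, 40.0])
        y = weibull(x, -1.0, 1.5)
        fit = CRCRegressor(family="weibull").fit(x, y)
        assert fit.alpha_ == pytest.approx(-1.0, abs=1e-4)
        assert fit.beta_ == pytest.approx(1.5, abs=1e-4)
        assert fit.quality_.r2 == pytest.approx(1.0, abs=1e-9)

    def test_ssr_beats_dense_grid_oracle(self, cr96_data):
        # brute-force 200x200 grid over the multi-start region
        x, y = cr96_data
        fit = CRCRegressor(family="weibull").fit(x, y)
        ssr_fit = float(np.sum((fit.predict(x) - y) ** 2))
        alphas = np.linspace(-12, 2, 200)
        betas = np.linspace(0.5, 12, 200)
        A, B = np.meshgrid(alphas, betas, indexing="ij")
        pred = 1 - np.exp(-np.exp(A[..., None] + B[..., None] * np.log10(x)))
        ssr_grid = float(np.min(np.sum((pred - y) ** 2, axis=-1)))
        assert ssr_fit <= ssr_grid + 1e-12

    def test_degenerate_all_dead_or_alive_rejected(self):
        x = np.array([0.1, 1.0, 10.0, 100.0])
        for value in (0.0, 1.0):
            with pytest.raises(DegenerateDataError):
                CRCRegressor(family="weibull").fit(x, np.full(4, value))

    def test_too_few_distinct_concentrations(self):
        x = np.array([1.0, 1.0, 2.0])
        y = np.array([0.1, 0.2, 0.9])
        with pytest.raises(CRCFitError, match="distinct"):
            CRCRegressor(family="gl").fit(x, y)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            CRCRegressor().fit([0.0, 1.0, 2.0, 4.0], [0.1, 0.3, 0.6, 0.9])

    def test_covariance_is_symmetric_psd(self, cr96_weibull_fit):
        C = cr96_weibull_fit.param_cov_
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) >= -1e-12)

    def test_sklearn_params_round_trip(self):
        est = CRCRegressor(family="gl", confidence=0.9)
        clone = CRCRegressor(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestSelectBestFamily:
    def test_nickel_96h_selects_generalised_logit(self):
        records = datasets.load_single_records("Ni", 96)
        fit = select_best_family(records)
        assert fit.family_ == "gl"

    def test_pure_weibull_data_prefers_fewer_parameters(self):
        # noise-free Weibull truth: no 3-parameter family can do better,
        # so the 2-parameter fit must win
        x = np.array([0.05, 0.2, 1.0, 3.0, 10.0, 40.0])
        y = weibull(x, -1.0, 1.5)
        fit = CRCRegressor(family="auto").fit(x, y)
        assert fit.family_ == "weibull"

    def test_fit_crc_named_family(self, cr96_data):
        records = datasets.load_single_records("Cr", 96)
        fit = fit_crc(records, "weibull")
        assert fit.family_ == "weibull"
        assert fit.quality_.r2 >= 0.96


class TestObservationBand:
    def test_band_contains_fit_and_has_floor(self, cr96_weibull_fit):
        fit = cr96_weibull_fit
        xs = np.logspace(-1.5, 1.5, 25)
        lo, hi = fit.observation_band(xs)
        yhat = fit.predict(xs)
        assert np.all(lo <= yhat) and np.all(yhat <= hi)
        # v C v^T >= 0, so half-width is at least t * s everywhere
        from scipy import stats

        t = stats.t.ppf(0.975, fit.n_points_ - fit.n_params_)
        floor = t * np.sqrt(fit.resid_var_)
        assert np.all((hi - lo) / 2 >= floor - 1e-12)

    def test_band_collapses_without_uncertainty(self):
        x = np.array([0.05, 0.2, 1.0, 3.0, 10.0, 40.0])
        y = weibull(x, -1.0, 1.5)
        fit = CRCRegressor(family="weibull").fit(x, y)
        lo, hi = fit.observation_band(x)
        assert np.allclose(lo, fit.predict(x), atol=1e-6)
        assert np.allclose(hi, fit.predict(x), atol=1e-6)

    def test_wider_at_higher_confidence(self, cr96_weibull_fit):
        xs = np.array([0.5, 1.0, 5.0])
        lo90, hi90 = cr96_weibull_fit.observation_band(xs, level=0.90)
        lo99, hi99 = cr96_weibull_fit.observation_band(xs, level=0.99)
        assert np.all(hi99 - lo99 > hi90 - lo90)

    def test_invalid_level_rejected(self, cr96_weibull_fit):
        with pytest.raises(ValueError, match="\\(0, 1\\)"):
            cr96_weibull_fit.observation_band([1.0], level=1.2)
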