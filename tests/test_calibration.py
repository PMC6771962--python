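"""Log-log calibration fitting and inverse prediction."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from rfduq.calibration import (
    CalibrationFit,
    CiKind,
    CohortPairs,
    fit_loglog,
    inverse_predict,
    pod_from_threshold,
)
from rfduq.rfd_core import Classification, Metric
from rfduq.synthetic_data import TshCohortParams, generate_tsh_cohort


def _fit_from_params(a, b, sigma, n, seed, x_log_mean=3.0, x_log_sd=1.0):
    params = TshCohortParams(
        n=n,
        exposure_log_mean=x_log_mean,
        exposure_log_sd=x_log_sd,
        intercept=a,
        slope=b,
        noise_log_sd=sigma,
        seed=seed,
    )
    pairs, _ = generate_tsh_cohort(params)
    return fit_loglog(pairs), pairs


class TestFitLoglog:
    def test_exact_line_recovered(self):
        serum = np.array([10.0, 100.0, 1000.0])
        a, b = 0.3, 0.5
        tsh = np.exp(a + b * np.log(serum))
        fit = fit_loglog(CohortPairs(serum, tsh))
        assert fit.slope == pytest.approx(b)
        assert fit.intercept == pytest.approx(a)
        assert fit.residual_se == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_ols(self, rng):
        """Independent OLS cross-check on random small data."""
        for _ in range(5):
            n = int(rng.integers(5, 20))
            serum = np.exp(rng.normal(3, 1, n))
            tsh = np.exp(rng.normal(1, 0.5, n))
            fit = fit_loglog(CohortPairs(serum, tsh))
            X = sm.add_constant(np.log(serum))
            res = sm.OLS(np.log(tsh), X).fit()
            assert fit.intercept == pytest.approx(res.params[0], rel=1e-9)
            assert fit.slope == pytest.approx(res.params[1], rel=1e-9)
            assert fit.residual_se == pytest.approx(np.sqrt(res.scale), rel=1e-9)

    def test_parameter_recovery_within_3_se(self):
        a, b, sigma = -0.4, 0.37, 0.5
        fit, pairs = _fit_from_params(a, b, sigma, n=1000, seed=5)
        se_slope = fit.residual_se / math.sqrt(fit.sxx_log)
        se_intercept = fit.residual_se * math.sqrt(
            1.0 / fit.n + fit.xbar_log**2 / fit.sxx_log
        )
        assert abs(fit.slope - b) < 3 * se_slope
        assert abs(fit.intercept - a) < 3 * se_intercept

    def test_nonpositive_values_rejected_with_row(self):
        with pytest.raises(ValueError, match="index 1"):
            CohortPairs(np.array([1.0, -2.0, 3.0]), np.array([1.0, 1.0, 1.0]))

    def test_zero_predictor_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_loglog(CohortPairs(np.array([5.0, 5.0, 5.0]), np.array([1.0, 2.0, 3.0])))


class TestInversePredict:
    def test_zero_noise_point_exact_and_ci_degenerate(self):
        serum = np.array([10.0, 50.0, 250.0, 1250.0])
        a, b = -0.4, 0.4
        tsh = np.exp(a + b * np.log(serum))
        fit = fit_loglog(CohortPairs(serum, tsh))
        pred = inverse_predict(fit, 5.0)
        expected = math.exp((math.log(5.0) - a) / b)
        assert pred.point == pytest.approx(expected)
        assert pred.ci_low == pytest.approx(pred.point, rel=1e-9)
        assert pred.ci_high == pytest.approx(pred.point, rel=1e-9)

    @pytest.mark.parametrize("threshold", [1.0, 5.0, 10.0])
    def test_forward_inverse_consistency(self, sampled_fit, threshold):
        pred = inverse_predict(sampled_fit, threshold)
        assert sampled_fit.predict_tsh(pred.point) == pytest.approx(threshold, rel=1e-10)

    def test_log_base_invariance(self, sampled_fit):
        """An independent base-10 reimplementation gives identical ppt values."""
        f = sampled_fit
        ln10 = math.log(10.0)
        # same fit re-expressed in base-10 logs
        slope10 = f.slope  # slope is base-invariant for log-log
        intercept10 = f.intercept / ln10
        y0_10 = math.log10(5.0)
        x0_10 = (y0_10 - intercept10) / slope10
        s10 = f.residual_se / ln10
        sxx10 = f.sxx_log / ln10**2
        ybar10 = f.ybar_log / ln10
        se10 = (s10 / abs(slope10)) * math.sqrt(
            1.0 / f.n + (y0_10 - ybar10) ** 2 / (slope10**2 * sxx10)
        )
        tcrit = stats.t.ppf(0.975, f.n - 2)
        lo10, hi10 = 10 ** (x0_10 - tcrit * se10), 10 ** (x0_10 + tcrit * se10)
        pred = inverse_predict(f, 5.0)
        assert pred.point == pytest.approx(10**x0_10, rel=1e-9)
        assert pred.ci_low == pytest.approx(lo10, rel=1e-9)
        assert pred.ci_high == pytest.approx(hi10, rel=1e-9)

    def test_methods_agree_when_slope_well_determined(self):
        # steep, tight fit: slope t-statistic far above 10
        fit, _ = _fit_from_params(0.0, 1.0, 0.1, n=200, seed=3)
        a = inverse_predict(fit, 5.0, method="approx_se")
        fb = inverse_predict(fit, 5.0, method="fieller")
        width_a = math.log(a.ci_high) - math.log(a.ci_low)
        width_f = math.log(fb.ci_high) - math.log(fb.ci_low)
        assert fb.kind is CiKind.INTERVAL
        assert abs(width_a - width_f) / width_f < 0.01

    def test_fieller_signals_unbounded_when_slope_indistinct(self, rng):
        # response unrelated to exposure: slope CI spans zero
        serum = np.exp(rng.normal(3, 1, 30))
        tsh = np.exp(rng.normal(1.0, 1.0, 30))
        fit = fit_loglog(CohortPairs(serum, tsh))
        t_slope = abs(fit.slope) / (fit.residual_se / math.sqrt(fit.sxx_log))
        assert t_slope < stats.t.ppf(0.975, fit.n - 2)  # premise of the case
        pred = inverse_predict(fit, 5.0, method="fieller")
        assert pred.kind in (CiKind.WHOLE_LINE, CiKind.COMPLEMENT)
        assert pred.upper_unbounded

    def test_chemcal_mode_widens_interval(self, sampled_fit):
        default = inverse_predict(sampled_fit, 5.0)
        with_replicate = inverse_predict(sampled_fit, 5.0, m=1)
        assert (with_replicate.ci_high / with_replicate.ci_low) > (
            default.ci_high / default.ci_low
        )

    def test_ci_width_monotone_in_n_and_noise(self):
        """Interval width shrinks with n and grows with residual noise."""
        widths_n = []
        for n in (20, 80, 320):
            fit, _ = _fit_from_params(-0.4, 0.37, 0.5, n=n, seed=9)
            p = inverse_predict(fit, 5.0)
            widths_n.append(math.log(p.ci_high / p.ci_low))
        assert widths_n[0] > widths_n[1] > widths_n[2]

        widths_s = []
        for sigma_scale in (0.5, 1.0, 2.0):
            fit, _ = _fit_from_params(-0.4, 0.37, 0.5, n=100, seed=9)
            scaled = CalibrationFit(
                slope=fit.slope,
                intercept=fit.intercept,
                residual_se=fit.residual_se * sigma_scale,
                n=fit.n,
                xbar_log=fit.xbar_log,
                ybar_log=fit.ybar_log,
                sxx_log=fit.sxx_log,
            )
            p = inverse_predict(scaled, 5.0)
            widths_s.append(math.log(p.ci_high / p.ci_low))
        assert widths_s[0] < widths_s[1] < widths_s[2]

    def test_threshold_at_fitted_mean_returns_mean_exposure(self, sampled_fit):
        threshold = math.exp(sampled_fit.ybar_log)
        pred = inverse_predict(sampled_fit, threshold)
        assert pred.point == pytest.approx(math.exp(sampled_fit.xbar_log), rel=1e-9)


class TestPodFromThreshold:
    def test_default_classifications(self, sampled_fit):
        pod5, _ = pod_from_threshold(sampled_fit, 5.0)
        pod10, _ = pod_from_threshold(sampled_fit, 10.0)
        assert pod5.classification is Classification.LOAEL
        assert pod10.classification is Classification.NOAEL
        assert pod10.dose.value > pod5.dose.value  # monotone when slope > 0
        assert pod5.dose.metric is Metric.TCDD

    def test_override_classification(self, sampled_fit):
        pod, _ = pod_from_threshold(sampled_fit, 5.0, classification=Classification.NOAEL)
        assert pod.classification is Classification.NOAEL

    def test_synthetic_curve_crosses_5_at_235(self, tcdd_params):
        """The default generating curve embeds the 5 uU/mL crossing at 235 ppt."""
        from rfduq.synthetic_data import population_fit

        pod, _ = pod_from_threshold(population_fit(tcdd_params), 5.0)
        assert pod.dose.value == pytest.approx(235.0, rel=1e-9)
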