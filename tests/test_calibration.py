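"""Retrieval, network-mean regressions, corrections, and drift."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmnet import calibration as cal
from pmnet.core import InsufficientDataError, ValidationError

from .conftest import phase_wide


class TestRetrieval:
    def test_zero_count_gives_retrieval_intercept(self):
        assert cal.count_to_mass(0) == pytest.approx(0.518, abs=1e-12)

    def test_thousand_counts(self):
        assert cal.count_to_mass(1000) == pytest.approx(3.258, abs=1e-9)

    @given(st.floats(min_value=0, max_value=1e6))
    def test_mass_count_round_trip(self, count):
        assert cal.mass_to_count(cal.count_to_mass(count)) == pytest.approx(count, rel=1e-9, abs=1e-6)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            cal.count_to_mass(-1.0)


class TestNetworkMean:
    def test_mean_and_quorum(self):
        idx = pd.date_range("2016-11-10", periods=3, freq="h")
        wide = pd.DataFrame({"a": [8.0, 8.0, np.nan], "b": [12.0, np.nan, np.nan]}, index=idx)
        mean = cal.network_mean(wide, min_sensors=2)
        assert list(mean) == [10.0]  # hours 2 and 3 fall below the quorum
        with pytest.raises(InsufficientDataError):
            cal.network_mean(wide.iloc[2:], min_sensors=2)


class TestSensorFits:
    def _series(self, values):
        return pd.Series(values, index=pd.date_range("2016-11-10", periods=len(values), freq="h"))

    def test_identity_fit(self):
        s = self._series([2.0, 4.0, 6.0])
        fit = cal.fit_sensor_vs_mean(s, s, min_hours=3)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse_vs_mean == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_fit(self):
        mean = self._series([2.0, 4.0, 6.0])
        sensor = self._series([3.0, 5.0, 7.0])
        fit = cal.fit_sensor_vs_mean(sensor, mean, min_hours=3)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        # RMSE is on raw differences, not regression residuals
        assert fit.rmse_vs_mean == pytest.approx(1.0)

    def test_zero_variance_mean_rejected(self):
        with pytest.raises(InsufficientDataError):
            cal.fit_sensor_vs_mean(self._series([1.0, 2.0, 3.0]), self._series([5.0, 5.0, 5.0]))


class TestPrecisionSummary:
    def test_two_constant_sensors_cv(self):
        idx = pd.date_range("2016-11-10", periods=10, freq="h")
        wide = pd.DataFrame({"a": 8.0, "b": 12.0}, index=idx)
        fits = {
            "a": cal.RegressionFit("a", "pre", 1, 0, 1.0, 2.0, 10),
            "b": cal.RegressionFit("b", "pre", 1, 0, 1.0, 2.0, 10),
        }
        out = cal.precision_summary(fits, wide)
        assert out["cv_mean"] == pytest.approx(np.std([8, 12], ddof=1) / 10, abs=1e-9)
        assert out["cv_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_sensors_have_zero_cv(self):
        idx = pd.date_range("2016-11-10", periods=5, freq="h")
        wide = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5]}, index=idx)
        fits = {s: cal.RegressionFit(s, "pre", 1, 0, 1.0, 0.0, 5) for s in "ab"}
        assert cal.precision_summary(fits, wide)["cv_mean"] == pytest.approx(0.0, abs=1e-12)


class TestCorrections:
    def _fit(self, slope, intercept, valid=True):
        return cal.RegressionFit("x", "pre", slope, intercept, 0.99, 0.5, 100, valid=valid)

    def test_average_of_pre_and_post(self):
        cf = cal.derive_correction(self._fit(0.91, 0.03), self._fit(0.96, -0.19))
        assert cf.slope == pytest.approx(0.935)
        assert cf.intercept == pytest.approx(-0.08)
        assert cf.source == "averaged"

    def test_average_second_example(self):
        cf = cal.derive_correction(self._fit(0.80, 2.64), self._fit(0.87, 1.37))
        assert cf.slope == pytest.approx(0.835)
        assert cf.intercept == pytest.approx(2.005)

    def test_pre_only_fallback(self):
        for post in (None, self._fit(1.2, 0.5, valid=False)):
            cf = cal.derive_correction(self._fit(1.0, 0.0), post)
            assert (cf.slope, cf.intercept, cf.source) == (1.0, 0.0, "pre_only")

    def test_invalid_pre_rejected(self):
        with pytest.raises(ValidationError):
            cal.derive_correction(self._fit(1.0, 0.0, valid=False))

    def test_apply_identity_and_example(self):
        ident = cal.CorrectionFactor("x", 1.0, 0.0, "averaged")
        assert cal.apply_correction(10.0, ident) == 10.0
        cf = cal.CorrectionFactor("x", 0.94, -0.08, "averaged")
        assert cal.apply_correction(10.0, cf) == pytest.approx(10.723, abs=5e-4)

    @given(
        st.floats(min_value=0.5, max_value=2.0),
        st.floats(min_value=-3.0, max_value=3.0),
    )
    def test_fit_then_correct_recovers_affine_transform(self, a, b):
        """A sensor that is exactly a*mean + b is restored to the mean."""
        rng = np.random.default_rng(11)
        idx = pd.date_range("2016-11-10", periods=200, freq="h")
        mean = pd.Series(rng.gamma(4.0, 3.0, 200), index=idx)
        sensor = a * mean + b
        fit = cal.fit_sensor_vs_mean(sensor, mean)
        corrected = cal.apply_correction(sensor, cal.derive_correction(fit))
        assert np.allclose(corrected, mean, atol=1e-8)

    def test_r2_invariant_rmse_not_under_correction(self):
        rng = np.random.default_rng(5)
        idx = pd.date_range("2016-11-10", periods=300, freq="h")
        mean = pd.Series(rng.gamma(4.0, 3.0, 300), index=idx)
        sensor = 1.3 * mean - 1.0 + pd.Series(rng.normal(0, 0.5, 300), index=idx)
        raw_fit = cal.fit_sensor_vs_mean(sensor, mean)
        corrected = cal.apply_correction(sensor, cal.derive_correction(raw_fit))
        corr_fit = cal.fit_sensor_vs_mean(corrected, mean)
        assert corr_fit.r2 == pytest.approx(raw_fit.r2, abs=1e-12)
        assert corr_fit.rmse_vs_mean < raw_fit.rmse_vs_mean


class TestDrift:
    def test_identical_fits_have_zero_drift(self):
        fit = cal.RegressionFit("x", "pre", 1.1, -0.4, 0.99, 0.5, 100)
        table = cal.drift_table(fit, fit)
        assert np.allclose(table["change_abs"], 0.0)
        assert np.allclose(table["change_pct"], 0.0)

    def test_drift_from_printed_collocation_coefficients(self):
        pre = cal.RegressionFit("13th Ave", "pre", 0.91, 0.03, 0.99, 0.38, 47)
        post = cal.RegressionFit("13th Ave", "post", 0.96, -0.19, 0.99, 0.69, 470)
        table = cal.drift_table(pre, post)
        row = table.loc[50.0]
        assert row["reading_pre"] == pytest.approx(45.53)
        assert row["reading_post"] == pytest.approx(47.81)
        assert row["change_abs"] == pytest.approx(2.28, abs=1e-9)
        assert row["change_pct"] == pytest.approx(5.01, abs=0.005)

        pre = cal.RegressionFit("Henrietta", "pre", 1.55, -1.17, 0.99, 0.60, 47)
        post = cal.RegressionFit("Henrietta", "post", 1.73, -0.51, 0.99, 0.59, 291)
        row5 = cal.drift_table(pre, post).loc[5.0]
        assert row5["reading_pre"] == pytest.approx(6.58)
        assert row5["reading_post"] == pytest.approx(8.14)
        assert row5["change_pct"] == pytest.approx(23.7, abs=0.05)

    def test_level_denominator_option(self):
        pre = cal.RegressionFit("x", "pre", 1.0, 0.0, 0.99, 0.5, 100)
        post = cal.RegressionFit("x", "post", 1.1, 0.0, 0.99, 0.5, 100)
        by_pre = cal.drift_table(pre, post)
        by_level = cal.drift_table(pre, post, pct_denominator="level")
        assert np.allclose(by_pre["change_pct"], by_level["change_pct"])  # slope-1 pre
        assert cal.drift_fraction_below([by_pre], threshold_pct=10.0) == 0.0


class TestOnSimulatedCampaign:
    def test_correction_shrinks_inter_sensor_spread(self, campaign_nogrowth):
        """With injected affine biases, corrected sensors agree with each
        other strictly better than raw sensors do."""
        wide = phase_wide(campaign_nogrowth, "pre").dropna()
        fits = cal.fit_period(wide, "pre")
        corrected = pd.DataFrame(
            {s: cal.apply_correction(wide[s], cal.derive_correction(f)) for s, f in fits.items()}
        )
        raw_rmse = []
        cor_rmse = []
        cols = list(wide.columns)[:8]
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                raw_rmse.append(np.sqrt(np.mean((wide[a] - wide[b]) ** 2)))
                cor_rmse.append(np.sqrt(np.mean((corrected[a] - corrected[b]) ** 2)))
        assert np.mean(cor_rmse) < np.mean(raw_rmse)
        assert np.max(cor_rmse) < np.max(raw_rmse)

    def test_network_mean_self_correction_is_identity(self, campaign_nogrowth):
        wide = phase_wide(campaign_nogrowth, "pre").dropna()
        mean = cal.network_mean(wide)
        fit = cal.fit_sensor_vs_mean(mean, mean)
        corrected = cal.apply_correction(mean, cal.derive_correction(fit))
        assert np.allclose(corrected, mean, atol=1e-10)
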