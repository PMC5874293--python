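import numpy as np
import pandas as pd
import pytest

import circannual as ca
from circannual.cosinor import reference_mesor
from circannual.pipeline import attach_sri
from circannual.thermal import (
    ThermalEffect,
    achieved_delta_t,
    compare_observed_predicted,
    estimate_thermal_effect,
    predict_from_temperature,
)


def _flat_series(name, offset=0.0, temp=10.0):
    ts = pd.date_range("2013-09-01", "2015-12-01", freq="6h")
    return ca.TemperatureSeries(name, ts, np.full(len(ts), temp + offset))


def _effect(slope=0.25, dt=2.0):
    return ThermalEffect(
        slope_per_c=slope, se_slope=0.05, achieved_delta_t=dt,
        heat_contrast=slope * dt, se_contrast=0.1, p_contrast=0.01, model="test",
    )


class TestEstimate:
    def test_slope_is_contrast_over_achieved_delta_t(self, meso_study):
        """A deterministic +0.5 SRI offset for heated fish with exactly +2
        degC loggers yields slope 0.25."""
        table, _ = attach_sri(meso_study.table, meso_study.polarity)
        df = table.df.copy()
        rng = np.random.default_rng(0)
        df["sri"] = rng.normal(0, 0.01, len(df)) + 0.5 * (
            df["heat_treatment"] == "heated"
        )
        flat = {
            t: _flat_series(t, offset=2.0 if (df.loc[df.tank_id == t,
                 "heat_treatment"].iloc[0] == "heated") else 0.0)
            for t in df["tank_id"].unique()
        }
        eff = estimate_thermal_effect(
            ca.ExpressionTable(df=df, genes=table.genes, origin=table.origin), flat
        )
        assert eff.achieved_delta_t == pytest.approx(2.0)
        assert eff.slope_per_c == pytest.approx(0.25, abs=0.01)

    def test_recovers_generated_slope_within_2se(self, meso_study):
        table, _ = attach_sri(meso_study.table, meso_study.polarity)
        eff = estimate_thermal_effect(table, meso_study.temps)
        truth = ca.effective_sri_truth(table, meso_study.config)
        assert abs(eff.slope_per_c - truth["thermal_slope_per_c"]) <= 3 * eff.se_slope
        assert eff.achieved_delta_t == pytest.approx(2.0, abs=0.2)

    def test_single_treatment_level_errors(self, meso_study):
        table, _ = attach_sri(meso_study.table, meso_study.polarity)
        df = table.df[table.df["heat_treatment"] == "heated"].reset_index(drop=True)
        with pytest.raises(ValueError, match="heated"):
            estimate_thermal_effect(
                ca.ExpressionTable(df=df, genes=table.genes, origin=table.origin),
                meso_study.temps,
            )

    def test_missing_tank_logs_error(self, meso_study):
        table, _ = attach_sri(meso_study.table, meso_study.polarity)
        with pytest.raises(ValueError, match="logger"):
            estimate_thermal_effect(table, {})

    def test_achieved_delta_t_from_paired_means(self):
        temps = {"a": _flat_series("a"), "b": _flat_series("b", offset=2.4)}
        assert achieved_delta_t(temps, ["b"]) == pytest.approx(2.4)


class TestPredict:
    def test_constant_temperature_gives_flat_series_at_mesor(self):
        pred = predict_from_temperature(
            _effect(), 3.0, _flat_series("x"),
            pd.date_range("2014-01-01", periods=6, freq="30D"),
        )
        np.testing.assert_allclose(pred.values, 3.0)

    def test_zero_slope_gives_flat_series(self):
        ts = pd.date_range("2013-09-01", "2015-01-01", freq="6h")
        temps = 10 + 5 * np.sin(np.arange(len(ts)) / 500.0)
        s = ca.TemperatureSeries("x", ts, temps)
        pred = predict_from_temperature(
            _effect(slope=0.0), 1.5, s,
            pd.date_range("2014-01-01", periods=6, freq="30D"),
        )
        np.testing.assert_allclose(pred.values, 1.5)

    def test_sinusoidal_temperature_closed_form(self):
        # T(t) = 10 + 4 cos(2 pi t/12): predictions follow slope * (Twk - mean)
        origin = pd.Timestamp("2014-01-01")
        ts = pd.date_range("2013-11-01", "2015-02-01", freq="1h")
        tm = np.asarray(ca.to_decimal_months(ts, origin))
        s = ca.TemperatureSeries("x", ts, 10 + 4 * np.cos(2 * np.pi * tm / 12))
        times = pd.DatetimeIndex(
            [origin + pd.Timedelta(days=30.4375 * m) for m in range(12)]
        )
        pred = predict_from_temperature(_effect(slope=0.5), 0.0, s, times)
        # amplitude of the predicted sinusoid ~ slope * A_T (prior-week
        # averaging slightly shrinks and lags the sinusoid)
        assert np.ptp(pred.values) / 2 == pytest.approx(0.5 * 4, rel=0.05)


class TestCompare:
    def _obs_fit(self):
        t = np.linspace(0, 11, 12)
        y = 1 + 2 * np.cos(2 * np.pi * t / 12 - 0.5)
        return ca.fit_cosinor(pd.DataFrame({"t_months": t, "y": y}), "y", covariates=())

    def test_identical_series_r_one_pct_hundred(self):
        fit = self._obs_fit()
        t = np.linspace(0, 11, 12)
        from circannual.cosinor import cosinor_predict

        pred = cosinor_predict(fit, t)
        comp = compare_observed_predicted(fit, t, pred)
        assert comp.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert comp.amplitude_pct == pytest.approx(100.0, rel=1e-9)

    def test_antiphase_gives_r_minus_one(self):
        fit = self._obs_fit()
        t = np.linspace(0, 11, 12)
        from circannual.cosinor import cosinor_predict

        pred = cosinor_predict(fit, (t + 6.0))
        comp = compare_observed_predicted(fit, t, pred)
        assert comp.pearson_r == pytest.approx(-1.0, abs=1e-9)

    def test_invariant_to_common_constant_shift(self):
        fit = self._obs_fit()
        t = np.linspace(0, 11, 12)
        pred = 0.3 * np.cos(2 * np.pi * t / 12 - 0.4)
        a = compare_observed_predicted(fit, t, pred)
        b = compare_observed_predicted(fit, t, pred + 57.0)
        assert b.pearson_r == pytest.approx(a.pearson_r, abs=1e-12)
        assert b.amplitude_pct == pytest.approx(a.amplitude_pct, rel=1e-9)

    def test_amplitude_pct_linear_in_slope(self):
        fit = self._obs_fit()
        t = np.linspace(0, 11, 12)
        base = np.cos(2 * np.pi * t / 12 - 0.2)
        a = compare_observed_predicted(fit, t, 0.5 * base)
        b = compare_observed_predicted(fit, t, 1.0 * base)
        assert b.amplitude_pct == pytest.approx(2 * a.amplitude_pct, rel=1e-9)

    def test_too_few_points_errors(self):
        fit = self._obs_fit()
        with pytest.raises(ValueError, match="4 grid points"):
            compare_observed_predicted(fit, [0.0, 1.0, 2.0], [0.0, 1.0, 2.0])


class TestEndToEnd:
    def test_purely_thermal_habitat_recovered(self, meso_study):
        """With no non-thermal seasonality, the thermal prediction nearly
        reproduces the observed sinusoid."""
        meso_cfg = ca.GeneratorConfig.mesocosm(
            seed=31, sri_thermal_slope_per_c=0.25, sri_amplitude=0.0,
            sri_residual_sd=0.5,
        )
        meso = ca.simulate_design(meso_cfg)
        mt, _ = attach_sri(meso.table, meso.polarity)
        eff = estimate_thermal_effect(mt, meso.temps)
        hab_cfg = ca.GeneratorConfig.wild(
            seed=32, sites=("FRN",), n_years=1, sri_amplitude=0.0,
            sri_thermal_slope_per_c=0.25, sri_residual_sd=0.5,
        )
        hab = ca.simulate_design(hab_cfg)
        ht, _ = attach_sri(hab.table, hab.polarity)
        obs = ca.fit_cosinor(ht, "sri")
        stimes = pd.DatetimeIndex(sorted(ht.df["sample_time"].unique()))
        pred = predict_from_temperature(
            eff, reference_mesor(obs), hab.temps["FRN"], stimes
        )
        tm = np.asarray(ca.to_decimal_months(stimes, hab.table.origin))
        comp = compare_observed_predicted(obs, tm, pred.values)
        assert comp.pearson_r > 0.9
        assert 60 <= comp.amplitude_pct <= 140
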