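import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import circannual as ca
from circannual.cosinor import (
    boxcox_lambda,
    cosinor_predict,
    fit_cosinor,
    reference_mesor,
    sinusoid_anova,
    wrap_phase,
)


def _sinusoid_df(t, y):
    return pd.DataFrame({"t_months": np.asarray(t, float), "y": np.asarray(y, float)})


class TestBoxCox:
    def test_lognormal_gives_lambda_near_zero(self):
        rng = np.random.default_rng(1)
        y = np.exp(rng.normal(0, 1, 500))
        assert -0.15 <= boxcox_lambda(y) <= 0.15

    def test_normal_shifted_gives_lambda_near_one(self):
        rng = np.random.default_rng(2)
        y = rng.normal(20, 2, 500)
        # independent oracle: scipy's MLE lambda, agreement within grid step
        lam = boxcox_lambda(y)
        _, lam_mle = stats.boxcox(y)
        assert abs(lam - lam_mle) <= 0.10
        assert 0.3 <= lam <= 1.7

    def test_constant_response_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            boxcox_lambda(np.full(10, 3.0))

    def test_non_positive_errors(self):
        with pytest.raises(ValueError):
            boxcox_lambda(np.array([1.0, -1.0, 2.0]))


class TestExactRecovery:
    def test_noise_free_sinusoid_recovered_exactly(self):
        t = np.linspace(0, 24, 120)
        y = 5 + 3 * np.cos(2 * np.pi * t / 12 - 0.6)
        fit = fit_cosinor(_sinusoid_df(t, y), "y", covariates=())
        assert fit.mesor == pytest.approx(5.0, abs=1e-10)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-10)
        assert fit.acrophase == pytest.approx(-0.6, abs=1e-10)

    @pytest.mark.parametrize(
        "beta,gamma,expect_A,expect_phi",
        [(3.0, 0.0, 3.0, 0.0), (0.0, -3.0, 3.0, np.pi / 2)],
    )
    def test_atan2_identities(self, beta, gamma, expect_A, expect_phi):
        t = np.linspace(0, 24, 100)
        om = 2 * np.pi / 12
        y = 1.0 + beta * np.cos(om * t) + gamma * np.sin(om * t)
        fit = fit_cosinor(_sinusoid_df(t, y), "y", covariates=())
        assert fit.amplitude == pytest.approx(expect_A, abs=1e-10)
        assert fit.acrophase == pytest.approx(expect_phi, abs=1e-10)

    def test_rank_deficient_design_names_columns(self, wild_table):
        df = wild_table.df.copy()
        df["dup"] = df["length_mm"]
        with pytest.raises(ValueError, match="aliased"):
            fit_cosinor(df, "sri", covariates=("sex", "length_mm", "dup"))

    def test_short_span_errors(self):
        t = np.linspace(0, 4, 50)
        y = np.sin(t)
        with pytest.raises(ValueError, match="half a period"):
            fit_cosinor(_sinusoid_df(t, y), "y", covariates=())


class TestPhaseEquivariance:
    @given(st.floats(min_value=-12.0, max_value=12.0))
    @settings(max_examples=25, deadline=None)
    def test_time_shift_rotates_acrophase(self, delta):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 24, 80))
        y = 2 + 1.5 * np.cos(2 * np.pi * t / 12 + 0.8) + rng.normal(0, 0.5, 80)
        f0 = fit_cosinor(_sinusoid_df(t, y), "y", covariates=())
        f1 = fit_cosinor(_sinusoid_df(t + delta, y), "y", covariates=())
        expected = wrap_phase(f0.acrophase - 2 * np.pi * delta / 12)
        got = wrap_phase(f1.acrophase)
        d = (got - expected + np.pi) % (2 * np.pi) - np.pi
        assert abs(d) < 1e-6


class TestPrediction:
    def test_peak_prediction_is_mesor_plus_amplitude(self, wild_table):
        fit = fit_cosinor(wild_table, "sri")
        pred = cosinor_predict(fit, [fit.peak_time], include="sinusoid")
        assert pred[0] == pytest.approx(reference_mesor(fit) + fit.amplitude, rel=1e-9)

    def test_period_average_is_mesor(self, wild_table):
        fit = fit_cosinor(wild_table, "sri")
        grid = np.linspace(0, 12, 20_001)[:-1]
        assert cosinor_predict(fit, grid).mean() == pytest.approx(
            reference_mesor(fit), abs=1e-6
        )

    def test_thermal_prediction_requires_thermal_term(self, wild_table):
        fit = fit_cosinor(wild_table, "sri")
        with pytest.raises(ValueError, match="thermal"):
            cosinor_predict(fit, [0.0], include="thermal")

    def test_full_prediction_is_additive(self, wild_table):
        fit = fit_cosinor(wild_table, "sri", thermal_col="temp_prior_wk")
        times = np.linspace(0, 11, 12)
        tvals = np.linspace(5, 15, 12)
        full = cosinor_predict(fit, times, include="full", thermal_values=tvals)
        sin_part = cosinor_predict(fit, times, include="sinusoid")
        th_part = cosinor_predict(fit, times, include="thermal", thermal_values=tvals)
        m = reference_mesor(fit)
        np.testing.assert_allclose(full, sin_part + th_part - m, rtol=1e-10)


class TestAnovaEffectSizes:
    def test_noise_free_sinusoid_eta2_is_one(self):
        t = np.linspace(0, 24, 60)
        y = 1 + 2 * np.cos(2 * np.pi * t / 12 + 1.0)
        fit = fit_cosinor(_sinusoid_df(t, y), "y", covariates=())
        assert sinusoid_anova(fit)["eta2_sinusoid"] == pytest.approx(1.0, abs=1e-9)

    def test_eta2_decreases_with_noise(self):
        rng = np.random.default_rng(4)
        t = np.tile(np.arange(12), 10).astype(float)
        base = 3 * np.cos(2 * np.pi * t / 12)
        means = []
        for sd in (0.5, 2.0, 8.0):
            vals = [
                fit_cosinor(
                    _sinusoid_df(t, base + rng.normal(0, sd, len(t))), "y", covariates=()
                ).eta2_sinusoid
                for _ in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_eta2_terms_bounded_and_sum_below_one(self, wild_table):
        fit = fit_cosinor(wild_table, "sri")
        a = sinusoid_anova(fit)
        for v in a["eta2_terms"].values():
            assert 0.0 <= v <= 1.0
        assert sum(a["eta2_terms"].values()) <= 1.0 + 1e-12


class TestDeltaMethodOracle:
    def test_linearized_fit_matches_grid_search_oracle(self):
        """(M, A, phi) from OLS equal the dense grid + refined NLS minimizer."""
        from .oracles import grid_search_cosinor

        rng = np.random.default_rng(17)
        for _ in range(4):
            n = int(rng.integers(60, 201))
            t = np.sort(rng.uniform(0, 24, n))
            y = (
                rng.normal(0, 3)
                + rng.uniform(0.5, 5) * np.cos(2 * np.pi * t / 12 + rng.uniform(-np.pi, np.pi))
                + rng.normal(0, 1.0, n)
            )
            fit = fit_cosinor(_sinusoid_df(t, y), "y", covariates=())
            M, A, phi = grid_search_cosinor(t, y, period=12.0)
            assert fit.mesor == pytest.approx(M, rel=1e-6, abs=1e-9)
            assert fit.amplitude == pytest.approx(A, rel=1e-6)
            d = (fit.acrophase - phi + np.pi) % (2 * np.pi) - np.pi
            assert abs(d) <= 1e-6 * max(1.0, abs(phi))
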