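import json

import numpy as np
import pandas as pd
import pytest

import circannual as ca
from circannual.data_model import write_expression_table
from circannual.simulate import (
    GeneratorConfig,
    ground_truth,
    residual_sd_for_eta2,
    simulate_design,
    simulate_temperature,
)


class TestTemperatureModel:
    def test_noise_free_series_is_exact_sinusoid(self):
        cfg = GeneratorConfig.wild()
        cfg.temperature.ar1_sd = 0.0
        cfg.temperature.diurnal_amplitude_c = 0.0
        rng = np.random.default_rng(0)
        s = simulate_temperature(cfg, "2013-10-01", "2014-10-01", rng)
        tm = np.asarray(ca.to_decimal_months(s.timestamps, cfg.origin))
        expected = (
            cfg.temperature.annual_mean_c
            + cfg.temperature.annual_amplitude_c
            * np.cos(2 * np.pi * tm / 12 + cfg.temperature.acrophase)
        )
        np.testing.assert_allclose(s.temps_c, expected, atol=1e-10)

    def test_heated_minus_unheated_is_constant_offset(self):
        cfg = GeneratorConfig.mesocosm()
        cfg.temperature.ar1_sd = 0.0
        rng = np.random.default_rng(0)
        cold = simulate_temperature(cfg, "2013-10-01", "2013-12-01", rng)
        hot = simulate_temperature(cfg, "2013-10-01", "2013-12-01", rng,
                                   heat_offset_c=2.0)
        np.testing.assert_allclose(hot.temps_c - cold.temps_c, 2.0, atol=1e-12)

    def test_ar1_autocorrelation_near_coefficient(self):
        cfg = GeneratorConfig.wild()
        cfg.temperature.annual_amplitude_c = 0.0
        cfg.temperature.diurnal_amplitude_c = 0.0
        rng = np.random.default_rng(1)
        s = simulate_temperature(cfg, "2013-10-01", "2014-10-01", rng)
        x = s.temps_c - s.temps_c.mean()
        acf1 = float(x[:-1] @ x[1:] / (x @ x))
        assert acf1 == pytest.approx(0.9, abs=0.05)

    def test_cadence_out_of_range_errors(self):
        cfg = GeneratorConfig.wild()
        with pytest.raises(ValueError, match="cadence"):
            simulate_temperature(cfg, "2013-10-01", "2013-10-02",
                                 np.random.default_rng(0), cadence_min=120)


class TestDesignFidelity:
    def test_lab_emits_exactly_120_balanced(self, lab_study):
        df = lab_study.table.df
        assert len(df) == 120
        cells = df.groupby(["temp_group", "pp_group"], observed=True).size()
        assert list(cells) == [30, 30, 30, 30]

    def test_wild_sampling_scheme(self, wild_study):
        df = wild_study.table.df
        per_month = df.groupby("sample_time", observed=True).size()
        assert (per_month == 10).all()
        assert len(per_month) == 12

    def test_mesocosm_quarter_balanced_tank_sampling(self, meso_study):
        df = meso_study.table.df.copy()
        df["quarter"] = (df["t_months"] // 3).astype(int)
        audit = df.groupby(["quarter", "tank_id"], observed=True).size()
        assert (audit == 5).all()
        per_month = df.groupby("sample_time", observed=True).size()
        assert (per_month == 20).all()

    def test_overdrawn_stock_errors(self):
        cfg = GeneratorConfig.mesocosm(stock_per_tank=10)
        with pytest.raises(ValueError, match="stocked"):
            simulate_design(cfg)

    def test_re_values_strictly_positive(self, meso_study):
        for g in meso_study.table.genes:
            assert (meso_study.table.df[f"re_{g}"] > 0).all()


class TestReproducibility:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = GeneratorConfig.mesocosm(seed=7)
        a = simulate_design(cfg)
        b = simulate_design(GeneratorConfig.mesocosm(seed=7))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_expression_table(a.table, pa)
        write_expression_table(b.table, pb)
        assert pa.read_bytes() == pb.read_bytes()
        for tank in a.temps:
            np.testing.assert_array_equal(a.temps[tank].temps_c, b.temps[tank].temps_c)

    def test_seed_change_changes_data_not_truth(self):
        a = simulate_design(GeneratorConfig.lab(seed=1))
        b = simulate_design(GeneratorConfig.lab(seed=2))
        assert not np.allclose(
            a.table.df["re_cd8a"].to_numpy(), b.table.df["re_cd8a"].to_numpy()
        )
        ta = {**a.truth, "config": {**a.truth["config"], "seed": 0}}
        tb = {**b.truth, "config": {**b.truth["config"], "seed": 0}}
        assert json.dumps(ta, sort_keys=True, default=str) == json.dumps(
            tb, sort_keys=True, default=str
        )

    def test_config_json_round_trip(self, tmp_path):
        cfg = GeneratorConfig.mesocosm(seed=5, sri_amplitude=1.7)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        back = GeneratorConfig.from_json(path)
        assert back == cfg


class TestCalibration:
    def test_residual_sd_helper_matches_eta2_identity(self):
        sd = residual_sd_for_eta2(3.95, 0.41)
        a2 = 3.95**2 / 2
        assert a2 / (a2 + sd**2) == pytest.approx(0.41, rel=1e-12)

    def test_generated_eta2_in_reported_regime(self):
        """Table-1-like settings keep the sinusoid effect size in the
        regime the field data showed (eta2 0.3-0.55)."""
        from circannual.pipeline import attach_sri

        vals = []
        for seed in range(8):
            cfg = GeneratorConfig.wild(
                seed=700 + seed, sites=("FRN",), n_years=1,
                sri_amplitude=3.95, sri_acrophase=-0.61,
                sri_residual_sd=residual_sd_for_eta2(3.95, 0.41),
            )
            st = simulate_design(cfg)
            table, _ = attach_sri(st.table, st.polarity)
            vals.append(ca.fit_cosinor(table, "sri").eta2_sinusoid)
        assert 0.3 <= np.mean(vals) <= 0.55

    def test_effective_truth_is_exact_identity(self, wild_study):
        """Realized SRI slope on any injected covariate equals the nominal
        slope times the standardization factor — checked by regressing the
        realized SRI on the known systematic signal."""
        from circannual.pipeline import attach_sri

        table, _ = attach_sri(wild_study.table, wild_study.polarity)
        truth = ca.effective_sri_truth(table, wild_study.config)
        df = table.df
        t = df["t_months"].to_numpy()
        cfg = wild_study.config
        signal = cfg.sri_amplitude * np.cos(2 * np.pi * t / 12 + cfg.sri_acrophase)
        slope = np.polyfit(signal, df["sri"].to_numpy(), 1)[0]
        assert slope == pytest.approx(truth["mean_scale"], abs=0.1)

    def test_ground_truth_per_gene_wiring(self):
        cfg = GeneratorConfig.mesocosm(sri_thermal_slope_per_c=0.36)
        truth = ground_truth(cfg)
        g = truth["per_gene"]["cd8a"]
        assert g["log10_thermal_slope_per_c"] == pytest.approx(0.36 / 12)
        assert g["polarity"] == 1
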