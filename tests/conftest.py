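import warnings

import numpy as np
import pandas as pd
import pytest

import circannual as ca
from circannual.pipeline import attach_sri

warnings.filterwarnings(
    "ignore", message="time span .* below one period", category=UserWarning
)


@pytest.fixture(scope="session")
def wild_study():
    """One-site, one-year wild study in the strong-seasonality regime."""
    cfg = ca.GeneratorConfig.wild(
        seed=11, sites=("FRN",), n_years=1,
        sri_amplitude=3.95, sri_acrophase=-0.61,
        sri_residual_sd=ca.residual_sd_for_eta2(3.95, 0.41),
    )
    return ca.simulate_design(cfg)


@pytest.fixture(scope="session")
def wild_table(wild_study):
    table, _ = attach_sri(wild_study.table, wild_study.polarity)
    return table


@pytest.fixture(scope="session")
def meso_study():
    cfg = ca.GeneratorConfig.mesocosm(seed=12, sri_thermal_slope_per_c=0.25)
    return ca.simulate_design(cfg)


@pytest.fixture(scope="session")
def lab_study():
    cfg = ca.GeneratorConfig.lab(seed=13)
    return ca.simulate_design(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


@pytest.fixture()
def simple_table(rng):
    """Small handmade expression table with two genes and known structure."""
    n = 48
    t = np.linspace(0, 12, n, endpoint=False)
    origin = pd.Timestamp("2013-10-01T12:00:00")
    df = pd.DataFrame(
        {
            "fish_id": [f"f{i}" for i in range(n)],
            "site": "A",
            "sample_time": [origin + pd.Timedelta(days=ti * 30.4375) for ti in t],
            "year": "Y1",
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "length_mm": rng.normal(45, 5, n),
            "plate_id": [f"P{i % 4}" for i in range(n)],
            "t_months": t,
            "re_g1": 10 ** rng.normal(0, 0.5, n),
            "re_g2": 10 ** rng.normal(0, 0.5, n),
        }
    )
    return ca.ExpressionTable(df=df, genes=("g1", "g2"), origin=origin)
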