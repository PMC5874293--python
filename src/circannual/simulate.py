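"""Synthetic study generator for the three designs the pipeline analyses.

Three sampling schemes are emulated with known ground truth:

* ``wild`` — two habitats sampled monthly (10 fish/month/site) across two
  annual cycles, with continuous water-temperature logging per habitat;
* ``mesocosm`` — 20 fish/month drawn from 12 outdoor tanks in a pattern
  that equalizes per-tank sampling within each quarter, under a 2 x 2
  heating (+2 degC) x ration treatment with per-tank loggers;
* ``lab`` — a 30-week 2 x 2 factorial of constant temperature (7/15 degC)
  and photoperiod regimen (natural vs x2 accelerated), one fish per
  treatment combination per week (n = 120), alternating replicate tanks.

Expression is generated on the log10 scale (so effects are multiplicative
on RE): a polarity-signed systematic signal specified on the scale of the
seasonal reporter index (SRI) is divided equally across the 12 reporter
genes, and gene-level noise, shared plate intercepts and tank effects are
added before exponentiation. Because the SRI z-scores each gene, the
realized SRI-scale effects equal the nominal targets divided by the
per-gene standardization SDs; ``effective_sri_truth`` computes that
realized truth exactly from a generated table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .data_model import (
    DAYS_PER_MONTH,
    ExpressionTable,
    GenePolarity,
    TemperatureSeries,
    mean_prior_week_temps,
    to_decimal_months,
)

#: The 12 reporter genes with their synthetic winter(-1)/summer(+1) polarity.
#: The split is a balanced synthetic assignment consistent with the genes'
#: described seasonal biases; polarity is an input to the analysis, not a
#: quantity the pipeline estimates.
DEFAULT_POLARITY: dict[str, int] = {
    "cd8a": 1, "ighm": 1, "foxp3b": 1, "igzh": 1, "il4": 1, "il12ba": 1,
    "tbk1": -1, "orai1": -1, "il1r_like": -1, "gpx4a": -1, "tirap": -1, "il17": -1,
}


def residual_sd_for_eta2(amplitude: float, eta2: float) -> float:
    """Residual SD giving an expected sinusoid eta^2 for a given amplitude.

    For a sinusoid sampled uniformly over its period the signal variance is
    A^2/2, so eta2 = (A^2/2) / (A^2/2 + sigma^2).
    """
    if not 0 < eta2 < 1:
        raise ValueError("eta2 must be in (0, 1)")
    return float(np.sqrt(amplitude**2 / 2.0 * (1.0 - eta2) / eta2))


@dataclass
class TemperatureModel:
    """Annual sinusoid + diurnal cycle + AR(1) noise water-temperature model."""

    annual_mean_c: float = 10.0
    annual_amplitude_c: float = 6.0
    acrophase: float = -0.086        # temperature peaks ~1 month before the SRI peak
    diurnal_amplitude_c: float = 0.5
    ar1_coef: float = 0.9
    ar1_sd: float = 0.3              # innovation SD
    cadence_min: int = 60


@dataclass
class GeneratorConfig:
    """Ground-truth parameters for one simulated study.

    Systematic effects (amplitude, thermal slope, covariate and treatment
    effects) are specified on the SRI scale and divided across the 12
    polarity-signed genes; noise terms are on the per-gene log10 scale
    except ``sri_residual_sd``.
    """

    seed: int = 0
    design: str = "wild"                   # wild | mesocosm | lab
    origin: str = "2013-10-01T12:00:00"
    # --- sampling schemes ---
    sites: tuple[str, ...] = ("FRN", "RHD")
    n_years: int = 2
    fish_per_month: int = 10               # wild, per site
    meso_fish_per_month: int = 20
    n_tanks: int = 12
    stock_per_tank: int = 40
    heat_offset_c: float = 2.0
    lab_n_weeks: int = 30
    lab_temps_c: tuple[float, float] = (7.0, 15.0)
    # --- SRI-scale systematic signal ---
    sri_amplitude: float = 3.95
    sri_acrophase: float = -0.61
    sri_thermal_slope_per_c: float = 0.0
    sri_residual_sd: float = 3.35          # ~= residual_sd_for_eta2(3.95, 0.41)
    sex_effect: float = 0.5
    length_slope_per_mm: float = 0.02
    ration_effect: float = 0.2
    year_effect: float = 0.0
    pp_effect: float = 0.0
    pp_doubles_frequency: bool = False
    # --- fish and assay structure ---
    length_mean_mm: float = 45.0
    length_sd_mm: float = 6.0
    length_drift_mm_per_month: float = 0.0
    n_plates: int = 10
    plate_sd: float = 0.05                 # per-gene log10 units
    tank_sd: float = 0.02
    heavy_tails: bool = False              # Student-t5 gene residuals
    temperature: TemperatureModel = field(default_factory=TemperatureModel)
    polarity: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_POLARITY))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.polarity)

    # --- design-appropriate presets -------------------------------------
    @classmethod
    def wild(cls, **kw) -> "GeneratorConfig":
        return cls(design="wild", **kw)

    @classmethod
    def mesocosm(cls, **kw) -> "GeneratorConfig":
        kw.setdefault("sri_amplitude", 1.0)
        kw.setdefault("sri_thermal_slope_per_c", 0.249)
        kw.setdefault("sri_residual_sd", 3.3)
        return cls(design="mesocosm", **kw)

    @classmethod
    def lab(cls, **kw) -> "GeneratorConfig":
        kw.setdefault("sri_amplitude", 0.0)
        kw.setdefault("sri_thermal_slope_per_c", 0.249)
        kw.setdefault("sri_residual_sd", 3.35)
        return cls(design="lab", **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        tm = d.pop("temperature", {})
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()},
                  temperature=TemperatureModel(**tm))
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def ground_truth(config: GeneratorConfig) -> dict:
    """Machine-readable generating truth: the config plus per-gene parameters.

    Depends only on the config (never on a realized dataset), so two seeds
    share an identical truth record.
    """
    n_genes = len(config.polarity)
    per_gene = {
        g: {
            "polarity": p,
            "log10_amplitude": config.sri_amplitude / n_genes,
            "log10_thermal_slope_per_c": config.sri_thermal_slope_per_c / n_genes,
            "acrophase": config.sri_acrophase,
            "residual_sd_log10": config.sri_residual_sd / np.sqrt(n_genes),
        }
        for g, p in config.polarity.items()
    }
    return {"config": config.to_dict(), "per_gene": per_gene}


def effective_sri_truth(
    table: ExpressionTable,
    config: GeneratorConfig,
    batch_key: tuple[str, ...] = ("site", "year"),
) -> dict:
    """Realized SRI-scale truth after per-gene standardization.

    The SRI divides each gene's log10 RE by its within-batch sample SD, so
    an injected SRI-scale effect c (split as c/12 per gene) is realized as
    c * (1/12) * sum_g 1/sd_g — an exact identity given the generated
    table. Returns the per-batch scale factors and the scaled targets.
    """
    df = table.df
    genes = config.genes
    keys = [k for k in batch_key if k in df.columns]
    groups = df.groupby(keys, observed=True).indices if keys else {(): np.arange(len(df))}
    factors = {}
    for batch, idx in groups.items():
        inv = 0.0
        for g in genes:
            logv = np.log10(df[f"re_{g}"].to_numpy(dtype=float)[idx])
            inv += 1.0 / logv.std(ddof=1)
        factors[batch if isinstance(batch, tuple) else (batch,)] = inv / len(genes)
    fbar = float(np.mean(list(factors.values())))
    return {
        "scale_factors": factors,
        "mean_scale": fbar,
        "amplitude": config.sri_amplitude * fbar,
        "acrophase": config.sri_acrophase,
        "thermal_slope_per_c": config.sri_thermal_slope_per_c * fbar,
        "residual_sd": config.sri_residual_sd * fbar,
    }


def simulate_temperature(
    config: GeneratorConfig,
    start,
    end,
    rng: np.random.Generator,
    heat_offset_c: float = 0.0,
    name: str = "site",
    cadence_min: int | None = None,
) -> TemperatureSeries:
    """Simulate a logger series: annual sinusoid + diurnal cycle + AR(1) noise."""
    tm = config.temperature
    cadence = cadence_min if cadence_min is not None else tm.cadence_min
    if not 1 <= cadence <= 60:
        raise ValueError("cadence must be between 1 and 60 minutes")
    ts = pd.date_range(start, end, freq=f"{cadence}min")
    t_months = np.asarray(to_decimal_months(ts, config.origin))
    hours = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    temps = (
        tm.annual_mean_c
        + tm.annual_amplitude_c * np.cos(2 * np.pi * t_months / 12.0 + tm.acrophase)
        + tm.diurnal_amplitude_c * np.cos(2 * np.pi * hours / 24.0)
        + heat_offset_c
    )
    if tm.ar1_sd > 0:
        burn = 200
        e = rng.normal(0.0, tm.ar1_sd, size=len(ts) + burn)
        noise = sp_signal.lfilter([1.0], [1.0, -tm.ar1_coef], e)[burn:]
        temps = temps + noise
    return TemperatureSeries(site_or_tank=name, timestamps=ts, temps_c=temps)


@dataclass
class SimulatedStudy:
    table: ExpressionTable
    temps: dict[str, TemperatureSeries]
    truth: dict
    polarity: GenePolarity
    config: GeneratorConfig


def _monthly_sample_times(origin: pd.Timestamp, n_months: int) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(
        [origin + pd.Timedelta(days=m * DAYS_PER_MONTH) for m in range(n_months)]
    )


def _gene_matrix(
    config: GeneratorConfig,
    rng: np.random.Generator,
    systematic_sri: np.ndarray,
    plate_ids: np.ndarray,
    tank_effects: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-gene RE columns from the SRI-scale systematic signal."""
    genes = config.genes
    n_genes = len(genes)
    n = len(systematic_sri)
    mesors = dict(zip(genes, np.linspace(-0.5, 0.5, n_genes)))
    plates = pd.unique(plate_ids)
    plate_b = dict(zip(plates, rng.normal(0.0, config.plate_sd, size=len(plates))))
    plate_vec = np.array([plate_b[p] for p in plate_ids])
    sd_e = config.sri_residual_sd / np.sqrt(n_genes)
    cols = {}
    for g in genes:
        if config.heavy_tails:
            e = rng.standard_t(5, size=n) * sd_e / np.sqrt(5.0 / 3.0)
        else:
            e = rng.normal(0.0, sd_e, size=n)
        log10_re = (
            mesors[g]
            + config.polarity[g] * systematic_sri / n_genes
            + plate_vec
            + tank_effects
            + e
        )
        cols[f"re_{g}"] = 10.0**log10_re
    return cols


def _common_covariates(config, rng, n, t_months):
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    length = (
        rng.normal(config.length_mean_mm, config.length_sd_mm, size=n)
        + config.length_drift_mm_per_month * t_months
    )
    length = np.clip(length, 15.0, None)
    return sex, length


def _systematic(config, t_months, twk_centered, sex, length, extra=0.0, omega_scale=1.0):
    omega = 2 * np.pi / 12.0 * omega_scale
    s = (
        config.sri_amplitude * np.cos(omega * t_months + config.sri_acrophase)
        + config.sri_thermal_slope_per_c * twk_centered
        + config.sex_effect * ((sex == "M").astype(float) - 0.5)
        + config.length_slope_per_mm * (length - config.length_mean_mm)
        + extra
    )
    return s


def simulate_design(config: GeneratorConfig, rng: np.random.Generator | None = None) -> SimulatedStudy:
    """Generate one study (expression table + temperature series + truth)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.design == "wild":
        study = _simulate_wild(config, rng)
    elif config.design == "mesocosm":
        study = _simulate_mesocosm(config, rng)
    elif config.design == "lab":
        study = _simulate_lab(config, rng)
    else:
        raise ValueError(f"unknown design {config.design!r}")
    return study


def _year_labels(n_months: int) -> list[str]:
    return [f"Y{m // 12 + 1}" for m in range(n_months)]


def _simulate_wild(config: GeneratorConfig, rng: np.random.Generator) -> SimulatedStudy:
    origin = pd.Timestamp(config.origin)
    n_months = 12 * config.n_years
    sample_times = _monthly_sample_times(origin, n_months)
    years = _year_labels(n_months)
    temps: dict[str, TemperatureSeries] = {}
    frames = []
    for site in config.sites:
        series = simulate_temperature(
            config,
            origin - pd.Timedelta(days=35),
            sample_times[-1] + pd.Timedelta(days=7),
            rng,
            name=site,
        )
        temps[site] = series
        twk_m = mean_prior_week_temps(series, sample_times)
        rows = {
            "sample_time": np.repeat(sample_times, config.fish_per_month),
            "site": site,
            "year": np.repeat(years, config.fish_per_month),
        }
        n = n_months * config.fish_per_month
        t_months = np.asarray(to_decimal_months(rows["sample_time"], origin))
        twk = np.repeat(twk_m, config.fish_per_month)
        sex, length = _common_covariates(config, rng, n, t_months)
        plate_ids = np.array(
            [f"{site}_{y}_P{rng.integers(config.n_plates)}"
             for y in rows["year"]]
        )
        s = _systematic(config, t_months, twk - twk.mean(), sex, length)
        gene_cols = _gene_matrix(config, rng, s, plate_ids, np.zeros(n))
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": [f"{site}_{i}" for i in range(n)],
                    **rows,
                    "sex": sex,
                    "length_mm": length,
                    "plate_id": plate_ids,
                    "t_months": t_months,
                    "temp_prior_wk": twk,
                    **gene_cols,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    table = ExpressionTable(df=df, genes=config.genes, origin=origin)
    return SimulatedStudy(table, temps, ground_truth(config), GenePolarity(dict(config.polarity)), config)


def _quarter_allocation(n_tanks: int, month_in_quarter: int) -> np.ndarray:
    """Fish count per tank for one month: 4 tanks give 1 fish, 8 give 2.

    The set of single-fish tanks rotates across the three months of the
    quarter, so each tank contributes 2 + 2 + 1 = 5 fish per quarter.
    """
    counts = np.full(n_tanks, 2, dtype=int)
    ones = slice(4 * month_in_quarter, 4 * month_in_quarter + 4)
    counts[ones] = 1
    return counts


def _simulate_mesocosm(config: GeneratorConfig, rng: np.random.Generator) -> SimulatedStudy:
    origin = pd.Timestamp(config.origin)
    n_months = 12 * config.n_years
    sample_times = _monthly_sample_times(origin, n_months)
    years = _year_labels(n_months)
    n_tanks = config.n_tanks
    if n_tanks % 4 != 0:
        raise ValueError("n_tanks must be a multiple of 4 for the 2x2 treatment layout")
    if config.meso_fish_per_month != 2 * n_tanks - 4:
        raise ValueError(
            "quarter-balanced allocation needs fish_per_month = 2*n_tanks - 4 "
            f"(got {config.meso_fish_per_month} for {n_tanks} tanks)"
        )
    per_tank_total = (config.meso_fish_per_month * n_months) // n_tanks
    if per_tank_total > config.stock_per_tank:
        raise ValueError(
            f"sampling scheme removes {per_tank_total} fish per tank but only "
            f"{config.stock_per_tank} are stocked"
        )
    heated = {f"T{k:02d}": k >= n_tanks // 2 for k in range(n_tanks)}
    ration = {
        f"T{k:02d}": ("low" if (k % (n_tanks // 2)) < n_tanks // 4 else "high")
        for k in range(n_tanks)
    }
    temps: dict[str, TemperatureSeries] = {}
    twk_by_tank = {}
    for tank, is_hot in heated.items():
        series = simulate_temperature(
            config,
            origin - pd.Timedelta(days=35),
            sample_times[-1] + pd.Timedelta(days=7),
            rng,
            heat_offset_c=config.heat_offset_c if is_hot else 0.0,
            name=tank,
        )
        temps[tank] = series
        twk_by_tank[tank] = mean_prior_week_temps(series, sample_times)

    tank_b = dict(
        zip(heated, rng.normal(0.0, config.tank_sd, size=n_tanks))
    )
    recs = []
    for m, (st, yr) in enumerate(zip(sample_times, years)):
        counts = _quarter_allocation(n_tanks, m % 3)
        for tank, c in zip(heated, counts):
            for _ in range(c):
                recs.append((st, yr, tank, m))
    df = pd.DataFrame(recs, columns=["sample_time", "year", "tank_id", "month_idx"])
    n = len(df)
    t_months = np.asarray(to_decimal_months(df["sample_time"], origin))
    twk = np.array([twk_by_tank[tk][m] for tk, m in zip(df["tank_id"], df["month_idx"])])
    sex, length = _common_covariates(config, rng, n, t_months)
    plate_ids = np.array(
        [f"M_{y}_P{rng.integers(config.n_plates)}" for y in df["year"]]
    )
    extra = (
        config.ration_effect
        * (df["tank_id"].map(ration).to_numpy() == "high").astype(float)
        + config.year_effect * (df["year"].to_numpy() == "Y2").astype(float)
    )
    s = _systematic(config, t_months, twk - twk.mean(), sex, length, extra=extra)
    tank_effects = df["tank_id"].map(tank_b).to_numpy()
    gene_cols = _gene_matrix(config, rng, s, plate_ids, tank_effects)
    out = pd.DataFrame(
        {
            "fish_id": [f"M_{i}" for i in range(n)],
            "site": "FRN-M",
            "sample_time": df["sample_time"],
            "year": df["year"],
            "sex": sex,
            "length_mm": length,
            "plate_id": plate_ids,
            "tank_id": df["tank_id"],
            "heat_treatment": df["tank_id"].map(
                lambda tk: "heated" if heated[tk] else "unheated"
            ),
            "ration": df["tank_id"].map(ration),
            "t_months": t_months,
            "temp_prior_wk": twk,
            **gene_cols,
        }
    )
    table = ExpressionTable(df=out, genes=config.genes, origin=origin)
    return SimulatedStudy(table, temps, ground_truth(config), GenePolarity(dict(config.polarity)), config)


def _simulate_lab(config: GeneratorConfig, rng: np.random.Generator) -> SimulatedStudy:
    origin = pd.Timestamp(config.origin)
    weeks = np.arange(config.lab_n_weeks)
    combos = [
        (tc, pp) for tc in config.lab_temps_c for pp in ("natural", "accelerated")
    ]
    recs = []
    for w in weeks:
        st = origin + pd.Timedelta(days=int(w) * 7)
        for ci, (tc, pp) in enumerate(combos):
            tank = f"L{ci}{'ab'[w % 2]}"  # two replicate tanks, alternating weekly
            recs.append((st, w, tc, pp, tank))
    df = pd.DataFrame(recs, columns=["sample_time", "week", "temp_c", "pp_group", "tank_id"])
    n = len(df)
    t_months = np.asarray(to_decimal_months(df["sample_time"], origin))
    sex, length = _common_covariates(config, rng, n, t_months)
    plate_ids = np.array([f"L_P{rng.integers(config.n_plates)}" for _ in range(n)])

    mean_temp = float(np.mean(config.lab_temps_c))
    twk_centered = df["temp_c"].to_numpy(dtype=float) - mean_temp
    accel = (df["pp_group"].to_numpy() == "accelerated")
    extra = config.pp_effect * accel.astype(float)
    omega = 2 * np.pi / 12.0
    sinusoid = np.where(
        accel & config.pp_doubles_frequency,
        config.sri_amplitude * np.cos(2 * omega * t_months + config.sri_acrophase),
        config.sri_amplitude * np.cos(omega * t_months + config.sri_acrophase),
    )
    s = (
        sinusoid
        + config.sri_thermal_slope_per_c * twk_centered
        + config.sex_effect * ((sex == "M").astype(float) - 0.5)
        + config.length_slope_per_mm * (length - config.length_mean_mm)
        + extra
    )
    tank_b = {tk: rng.normal(0.0, config.tank_sd) for tk in df["tank_id"].unique()}
    gene_cols = _gene_matrix(config, rng, s, plate_ids, df["tank_id"].map(tank_b).to_numpy())

    # photoperiod as % of 24 h (square-wave day length advancing daily;
    # generated as a covariate with zero effect by default)
    doy = df["sample_time"].dt.dayofyear.to_numpy()
    rate = np.where(accel, 2.0, 1.0)
    doy_eff = (doy[0] + rate * (doy - doy[0])) % 365.25
    # day length as % of 24 h, minimum near the winter solstice (~33%)
    daylength_pct = 50.0 - 17.0 * np.cos(2 * np.pi * (doy_eff + 10.0) / 365.25)

    out = pd.DataFrame(
        {
            "fish_id": [f"L_{i}" for i in range(n)],
            "site": "LAB",
            "sample_time": df["sample_time"],
            "year": "Y1",
            "sex": sex,
            "length_mm": length,
            "plate_id": plate_ids,
            "tank_id": df["tank_id"],
            "temp_group": df["temp_c"].map(lambda v: f"{v:g}C"),
            "pp_group": df["pp_group"],
            "daylength_pct": daylength_pct,
            "t_months": t_months,
            **gene_cols,
        }
    )
    table = ExpressionTable(df=out, genes=config.genes, origin=origin)
    return SimulatedStudy(table, {}, ground_truth(config), GenePolarity(dict(config.polarity)), config)
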