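"""End-to-end report assembly: field (wild/mesocosm) and laboratory analyses.

The field workflow follows the two-stage strategy of the analyses this
package implements: a penalized-spline trend fit first, and a cosinor
regression only where the temporal smoother is significant (a flag
disables the gating for sensitivity analyses). The laboratory workflow
runs the nested model comparison per response, per-gene thermal contrasts
and the photoperiod-group smoother difference test.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cosinor import fit_cosinor, reference_mesor
from .data_model import ExpressionTable, TemperatureSeries
from .gam import fit_pgam, smoother_difference
from .ppmodels import fit_model_set, temperature_effect_summary
from .sri import SriResult, compute_sri
from .thermal import (
    ThermalEffect,
    compare_observed_predicted,
    predict_from_temperature,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    period: float = 12.0
    alpha: float = 0.05
    k: int = 10
    boxcox: str = "off"
    batch_key: tuple[str, ...] = ("site", "year")
    gate_cosinor_on_smoother: bool = True
    plate_random: bool = True
    covariates: tuple[str, ...] = ("sex", "length_mm")

    def to_dict(self) -> dict:
        return {
            "period": self.period, "alpha": self.alpha, "k": self.k,
            "boxcox": self.boxcox, "batch_key": list(self.batch_key),
            "gate_cosinor_on_smoother": self.gate_cosinor_on_smoother,
            "plate_random": self.plate_random, "covariates": list(self.covariates),
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_field_analysis(
    table: ExpressionTable,
    response: str = "sri",
    config: PipelineConfig | None = None,
    temps: dict[str, TemperatureSeries] | None = None,
    thermal_effect: ThermalEffect | None = None,
) -> pd.DataFrame:
    """Per site x year: smoother stats, then (gated) cosinor stats.

    ``response`` must already be a column of the table (attach the SRI with
    :func:`circannual.sri.SriResult.attach` first). When a thermal effect
    and habitat temperature series are supplied, the observed-vs-thermally-
    predicted comparison is appended per row.
    """
    cfg = config or PipelineConfig()
    df = table.df
    extra_covs = [c for c in ("heat_treatment", "ration") if c in df.columns]
    rows = []
    for (site, year), idx in df.groupby(["site", "year"], observed=True).indices.items():
        sub = ExpressionTable(df=df.iloc[idx].reset_index(drop=True), genes=table.genes,
                              origin=table.origin)
        covs = tuple(cfg.covariates) + tuple(
            c for c in extra_covs
            if sub.df[c].nunique() > 1
        )
        gfit = fit_pgam(sub, response, covariates=covs, k=cfg.k,
                        plate_random=cfg.plate_random)
        row: dict = {
            "site": site, "year": year, "n": sub.n,
            "delta_dev_pct": gfit.delta_deviance_pct,
            "p_smooth": gfit.p_smooth,
            "edf": gfit.edf,
        }
        smoother_ok = gfit.p_smooth < cfg.alpha
        if smoother_ok or not cfg.gate_cosinor_on_smoother:
            cfit = fit_cosinor(sub, response, covariates=covs, period=cfg.period,
                               boxcox=cfg.boxcox)
            row.update(
                acrophase=cfit.acrophase, se_acrophase=cfit.se_acrophase,
                amplitude=cfit.amplitude, se_amplitude=cfit.se_amplitude,
                p_sinusoid=cfit.p_sinusoid, eta2_pct=100 * cfit.eta2_sinusoid,
            )
            if thermal_effect is not None and temps and site in temps:
                sample_times = pd.DatetimeIndex(sub.df["sample_time"].unique()).sort_values()
                pred = predict_from_temperature(
                    thermal_effect, reference_mesor(cfit), temps[site], sample_times
                )
                t_m = np.asarray(
                    (sample_times - table.origin).total_seconds()
                ) / (30.4375 * 86400.0)
                comp = compare_observed_predicted(cfit, t_m, pred.values)
                row.update(pearson_r=comp.pearson_r, amplitude_pct=comp.amplitude_pct)
        else:
            row.update(
                acrophase=np.nan, se_acrophase=np.nan, amplitude=np.nan,
                se_amplitude=np.nan, p_sinusoid=np.nan, eta2_pct=np.nan,
                note="ns smoother; cosinor not run",
            )
        rows.append(row)
    report = pd.DataFrame(rows)
    logger.info("field analysis: %d site-year fits (config %s)", len(report), cfg.hash())
    return report


def run_lab_analysis(
    table: ExpressionTable,
    responses: tuple[str, ...] | list[str] = ("sri",),
    config: PipelineConfig | None = None,
    gene_boxcox: bool = True,
) -> dict:
    """Laboratory experiment report: model set, thermal contrasts, PP smoother test."""
    cfg = config or PipelineConfig()
    df = table.df
    if "pp_group" not in df.columns:
        raise ValueError("laboratory table needs a pp_group column")
    model_rows = []
    diffs = {}
    for resp in responses:
        bc = "auto" if (gene_boxcox and resp.startswith("re_")) else "off"
        mc = fit_model_set(table, resp, period=cfg.period, boxcox=bc, alpha=cfg.alpha)
        for name in ("null", "model1", "model2"):
            m = mc.models[name]
            model_rows.append(
                {
                    "response": resp, "model": name, "aic": m["aic"],
                    "p": {"null": np.nan, "model1": mc.p_model1_vs_null,
                          "model2": mc.p_model2_vs_model1}[name],
                    "eta2_pct": 100 * mc.eta2_model1_sinusoid if name == "model1" else np.nan,
                    "verdict": mc.verdict if name == "model2" else "",
                }
            )
        d = smoother_difference(
            table, resp if bc == "off" else resp, "pp_group",
            covariates=tuple(cfg.covariates) + ("temp_group",), k=cfg.k,
        )
        diffs[resp] = d
    thermal_rows = [
        temperature_effect_summary(table, f"re_{g}", period=cfg.period, k=cfg.k)
        for g in table.genes
    ]
    return {
        "model_comparison": pd.DataFrame(model_rows),
        "smoother_differences": diffs,
        "thermal_contrasts": thermal_rows,
        "config": cfg.to_dict(),
    }


def attach_sri(table: ExpressionTable, polarity, batch_key=("site", "year")) -> tuple[ExpressionTable, SriResult]:
    """Convenience: compute the SRI and return the table with it attached."""
    res = compute_sri(table, polarity, batch_key=batch_key)
    return res.attach(table), res
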