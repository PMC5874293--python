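"""Nested model comparison for the laboratory photoperiod experiment.

Three nested OLS models separate temperature, endogenous-time and
photoperiod hypotheses:

* null    — sex + length + temperature treatment;
* model 1 — null + cos(2 pi t / tau) + sin(2 pi t / tau), a photoperiod-
            independent endogenous circannual trend;
* model 2 — model 1 + photoperiod group + its interactions with the two
            sinusoid columns (changed amplitude/phase or loss of
            oscillation in the accelerated group).

The verdict tests the photoperiod interaction first (model 2 vs model 1),
then the endogenous trend (model 1 vs null), both by F-test at a
configurable alpha. AIC is computed from the Gaussian log-likelihood with
the residual variance counted as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._design import build_design, check_full_rank
from .cosinor import boxcox_lambda, boxcox_transform, fit_cosinor
from .data_model import ExpressionTable
from .gam import fit_pgam


def gaussian_aic(rss: float, n: int, n_coef: int) -> float:
    """AIC for a Gaussian model with MLE variance; k counts sigma^2."""
    sigma2 = rss / n
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return float(-2 * llf + 2 * (n_coef + 1))


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _nested_f(rss_small: float, rss_big: float, df_diff: int, df_resid_big: float) -> float:
    if rss_big <= 0 or df_resid_big <= 0:
        return float("nan")
    f = ((rss_small - rss_big) / df_diff) / (rss_big / df_resid_big)
    return float(stats.f.sf(max(f, 0.0), df_diff, df_resid_big))


@dataclass
class ModelComparisonResult:
    models: dict[str, dict]            # per model: aic, rss, df_resid, n_coef
    p_model1_vs_null: float
    p_model2_vs_model1: float
    eta2_model1_sinusoid: float
    verdict: str                       # no_temporal_effect | endogenous_trend | pp_effect
    alpha: float
    boxcox_lambda: float | None
    n: int
    response: str

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "n": self.n,
            "models": self.models,
            "p_model1_vs_null": self.p_model1_vs_null,
            "p_model2_vs_model1": self.p_model2_vs_model1,
            "eta2_model1_sinusoid": self.eta2_model1_sinusoid,
            "verdict": self.verdict,
            "alpha": self.alpha,
            "boxcox_lambda": self.boxcox_lambda,
        }


def fit_model_set(
    lab_table: ExpressionTable | pd.DataFrame,
    response: str,
    period: float = 12.0,
    time_col: str = "t_months",
    boxcox: str = "off",
    alpha: float = 0.05,
) -> ModelComparisonResult:
    """Fit the null / endogenous / photoperiod model set on one response.

    Box-Cox (``boxcox="auto"``) is estimated once on the raw response and
    the same transform is used for all three models, so AICs are
    comparable. Gene responses are conventionally transformed; a z-score
    index like the SRI is not (it can be negative).
    """
    df = lab_table.df if isinstance(lab_table, ExpressionTable) else lab_table
    for col in ("temp_group", "pp_group"):
        if col not in df.columns:
            raise ValueError(f"laboratory table needs a {col!r} column")
    cells = df.groupby(["temp_group", "pp_group"], observed=True).size()
    if len(cells) != 4 or (cells == 0).any():
        raise ValueError(
            f"unbalanced or missing treatment cells (need all 4 temp x pp combinations, "
            f"got {len(cells)})"
        )

    y = df[response].to_numpy(dtype=float)
    lam: float | None = None
    if boxcox == "auto":
        lam = boxcox_lambda(y)
        y = boxcox_transform(y, lam)

    n = len(y)
    t = df[time_col].to_numpy(dtype=float)
    omega = 2 * np.pi / period

    base = build_design(df, ["sex", "length_mm", "temp_group"])
    X0 = base.matrix.copy()
    X1 = X0.copy()
    X1["cos"] = np.cos(omega * t)
    X1["sin"] = np.sin(omega * t)
    pp = build_design(df, ["pp_group"], add_intercept=False)
    pp_col = pp.terms["pp_group"][0]
    X2 = X1.copy()
    X2[pp_col] = pp.matrix[pp_col]
    X2[f"cos:{pp_col}"] = X2["cos"] * X2[pp_col]
    X2[f"sin:{pp_col}"] = X2["sin"] * X2[pp_col]
    for X in (X0, X1, X2):
        check_full_rank(X)

    models = {}
    rss = {}
    for name, X in (("null", X0), ("model1", X1), ("model2", X2)):
        arr = X.to_numpy(dtype=float)
        _, r = _ols(arr, y)
        rss[name] = r
        models[name] = {
            "aic": gaussian_aic(r, n, arr.shape[1]),
            "rss": r,
            "df_resid": n - arr.shape[1],
            "n_coef": arr.shape[1],
        }

    p1 = _nested_f(rss["null"], rss["model1"], 2, models["model1"]["df_resid"])
    p2 = _nested_f(rss["model1"], rss["model2"], 3, models["model2"]["df_resid"])

    ss_total = float(np.sum((y - y.mean()) ** 2))
    eta2_sin = (rss["null"] - rss["model1"]) / ss_total if ss_total > 0 else float("nan")

    if np.isfinite(p2) and p2 < alpha:
        verdict = "pp_effect"
    elif np.isfinite(p1) and p1 < alpha:
        verdict = "endogenous_trend"
    else:
        verdict = "no_temporal_effect"

    return ModelComparisonResult(
        models=models,
        p_model1_vs_null=p1,
        p_model2_vs_model1=p2,
        eta2_model1_sinusoid=float(max(eta2_sin, 0.0)),
        verdict=verdict,
        alpha=alpha,
        boxcox_lambda=lam,
        n=n,
        response=response,
    )


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional multiplicity control for gene batches)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0, 1)
    return out


def temperature_effect_summary(
    lab_table: ExpressionTable | pd.DataFrame,
    gene: str,
    period: float = 12.0,
    time_col: str = "t_months",
    boxcox: str = "auto",
    k: int = 10,
) -> dict:
    """The 15-vs-7 degC contrast on one response, from both model families.

    Reports the temperature-treatment coefficient from (a) the cosinor-
    style linear model (sex + length + temp + sinusoid) with its eta^2 and
    (b) the parallel penalized-spline fit, with the smoother's deviance
    share. The response is Box-Cox transformed when ``boxcox="auto"``.
    """
    df = lab_table.df if isinstance(lab_table, ExpressionTable) else lab_table
    if "temp_group" not in df.columns:
        raise ValueError("laboratory table needs a temp_group column")
    levels = [lv for lv in pd.Categorical(df["temp_group"]).categories
              if (df["temp_group"] == lv).any()]
    if len(levels) != 2:
        raise ValueError(f"temp_group must have exactly 2 observed levels, got {levels}")

    work = df.copy()
    lam: float | None = None
    y = work[gene].to_numpy(dtype=float)
    if boxcox == "auto":
        lam = boxcox_lambda(y)
        work[gene] = boxcox_transform(y, lam)

    cfit = fit_cosinor(
        work, gene, covariates=("sex", "length_mm", "temp_group"),
        period=period, time_col=time_col, boxcox="off",
    )
    temp_col = cfit.design.terms["temp_group"][0]
    row = cfit.coefficients.loc[temp_col]

    gfit = fit_pgam(
        work, gene, covariates=("sex", "length_mm", "temp_group"),
        k=k, time_col=time_col,
    )
    grow = gfit.parametric.loc[temp_col]

    return {
        "gene": gene,
        "contrast": f"{temp_col} (vs {levels[0]})",
        "boxcox_lambda": lam,
        "cosinor": {
            "coef": float(row["coef"]), "se": float(row["se"]), "p": float(row["p"]),
            "eta2": float(cfit.eta2_terms.get("temp_group", np.nan)),
        },
        "pgam": {
            "coef": float(grow["coef"]), "se": float(grow["se"]), "p": float(grow["p"]),
            "delta_deviance_pct": gfit.delta_deviance_pct,
        },
    }
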