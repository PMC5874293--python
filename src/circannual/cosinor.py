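"""Linearized cosinor regression with covariates.

The seasonal sinusoid Y(t) = M + A cos(2 pi t / tau + phi) + e(t) is fitted
by ordinary least squares after the standard linearization

    Y = M + beta * cos(2 pi t / tau) + gamma * sin(2 pi t / tau) + ...,

with beta = A cos(phi) and gamma = -A sin(phi). Amplitude and acrophase
standard errors come from the delta method applied to the (beta, gamma)
covariance; the sinusoid's significance is the joint F-test of the two
linearized columns, and effect sizes are classical eta^2 with Type II sums
of squares. An optional Box-Cox transform (profile-likelihood grid) is
available for individual-gene responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._design import DesignInfo, build_design, check_full_rank
from .data_model import ExpressionTable

BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.05), 2)


def boxcox_lambda(y) -> float:
    """Box-Cox lambda maximizing the profile log-likelihood on a [-2, 2] grid.

    The transform is (y^lambda - 1)/lambda, or ln(y) at lambda = 0.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive responses")
    if np.ptp(y) == 0:
        raise ValueError("zero variance response; Box-Cox lambda undefined")
    llf = np.array([stats.boxcox_llf(lam, y) for lam in BOXCOX_GRID])
    return float(BOXCOX_GRID[np.argmax(llf)])


def boxcox_transform(y, lam: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive responses")
    if lam == 0.0:
        return np.log(y)
    return (y**lam - 1.0) / lam


def wrap_phase(phi: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    phi = (phi + np.pi) % (2 * np.pi) - np.pi
    if phi == -np.pi:
        phi = np.pi
    return float(phi)


@dataclass
class CosinorFit:
    """Result of a covariate-adjusted cosinor regression.

    ``acrophase`` is in radians, wrapped to (-pi, pi]; the fitted curve
    peaks at t* = (-acrophase * period) / (2 pi) mod period.
    """

    mesor: float
    amplitude: float
    acrophase: float
    se_amplitude: float
    se_acrophase: float
    beta: float
    gamma: float
    cov_bg: np.ndarray          # 2x2 covariance of (beta, gamma)
    period: float
    p_sinusoid: float
    eta2_sinusoid: float
    coefficients: pd.DataFrame  # coef, se, p per design column
    eta2_terms: dict[str, float]
    boxcox_lambda: float | None
    n: int
    response: str
    design: DesignInfo = field(repr=False)
    sigma2: float = field(repr=False, default=np.nan)
    rss: float = field(repr=False, default=np.nan)
    ss_total: float = field(repr=False, default=np.nan)
    thermal_col: str | None = None

    @property
    def peak_time(self) -> float:
        return float((-self.acrophase * self.period / (2 * np.pi)) % self.period)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "n": self.n,
            "period": self.period,
            "mesor": self.mesor,
            "amplitude": self.amplitude,
            "acrophase": self.acrophase,
            "se_amplitude": self.se_amplitude,
            "se_acrophase": self.se_acrophase,
            "beta": self.beta,
            "gamma": self.gamma,
            "p_sinusoid": self.p_sinusoid,
            "eta2_sinusoid": self.eta2_sinusoid,
            "boxcox_lambda": self.boxcox_lambda,
            "peak_time": self.peak_time,
            "coefficients": {
                name: {"coef": float(r["coef"]), "se": float(r["se"]), "p": float(r["p"])}
                for name, r in self.coefficients.iterrows()
            },
        }


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def fit_cosinor(
    table: ExpressionTable | pd.DataFrame,
    response: str,
    covariates: tuple[str, ...] | list[str] = ("sex", "length_mm"),
    period: float = 12.0,
    time_col: str = "t_months",
    boxcox: str = "off",
    thermal_col: str | None = None,
) -> CosinorFit:
    """Fit the linearized cosinor model by OLS.

    Parameters
    ----------
    table
        Expression table (or bare DataFrame) with the response, a decimal-
        month time column, and the covariates.
    response
        Response column name (e.g. ``"sri"`` or ``"re_cd8a"``).
    covariates
        Additional fixed effects; categorical columns are dummy-coded.
    period
        Sinusoid period tau in months (12 = one year).
    boxcox
        ``"auto"`` estimates a Box-Cox lambda on the response first (meant
        for individual-gene responses); ``"off"`` fits the raw response.
    thermal_col
        Optional numeric column treated as the thermal term (used by
        thermal-only predictions).
    """
    df = table.df if isinstance(table, ExpressionTable) else table
    if response not in df.columns:
        raise KeyError(f"response column {response!r} not in table")
    if time_col not in df.columns:
        raise KeyError(f"time column {time_col!r} not in table; attach a time coordinate")

    y = df[response].to_numpy(dtype=float)
    lam: float | None = None
    if boxcox == "auto":
        lam = boxcox_lambda(y)
        y = boxcox_transform(y, lam)

    t = df[time_col].to_numpy(dtype=float)
    covs = list(covariates) + ([thermal_col] if thermal_col else [])
    design = build_design(df, covs)
    omega = 2 * np.pi / period
    X = design.matrix.copy()
    X.insert(1, "cos", np.cos(omega * t))
    X.insert(2, "sin", np.sin(omega * t))
    design.terms = {"const": ["const"], "sinusoid": ["cos", "sin"],
                    **{k: v for k, v in design.terms.items() if k != "const"}}
    design.matrix = X

    p = X.shape[1]
    if len(y) < p + 1:
        raise ValueError(f"need at least {p + 1} rows to fit {p} coefficients")
    span = np.ptp(t)
    if span < period / 2:
        raise ValueError(f"time span {span:.2f} months is below half a period")
    if span < period:
        warnings.warn(
            f"time span {span:.2f} months is below one period; amplitude and "
            "acrophase are weakly identified",
            stacklevel=2,
        )
    check_full_rank(X)

    model = sm.OLS(y, X.to_numpy(dtype=float))
    res = model.fit()
    names = list(X.columns)
    coef = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)

    beta, gamma = float(coef["cos"]), float(coef["sin"])
    amplitude = float(np.hypot(beta, gamma))
    acrophase = wrap_phase(np.arctan2(-gamma, beta))
    Vbg = cov.loc[["cos", "sin"], ["cos", "sin"]].to_numpy()
    if amplitude > 0:
        se_amp = float(
            np.sqrt(
                (beta**2 * Vbg[0, 0] + 2 * beta * gamma * Vbg[0, 1] + gamma**2 * Vbg[1, 1])
            )
            / amplitude
        )
        se_phi = float(
            np.sqrt(
                (gamma**2 * Vbg[0, 0] - 2 * beta * gamma * Vbg[0, 1] + beta**2 * Vbg[1, 1])
            )
            / amplitude**2
        )
    else:
        se_amp = se_phi = float("nan")

    # joint F-test of the two sinusoid columns
    R = np.zeros((2, p))
    R[0, names.index("cos")] = 1.0
    R[1, names.index("sin")] = 1.0
    ftest = res.f_test(R)
    p_sin = float(ftest.pvalue)

    # Type II eta^2 per term: SS = RSS(model without term) - RSS(full)
    Xarr = X.to_numpy(dtype=float)
    rss_full = float(res.ssr)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    eta2_terms: dict[str, float] = {}
    for term, tcols in design.terms.items():
        if term == "const" or not tcols:
            continue
        keep = [i for i, nm in enumerate(names) if nm not in tcols]
        ss_term = _ols_rss(Xarr[:, keep], y) - rss_full
        eta2_terms[term] = max(ss_term, 0.0) / ss_total if ss_total > 0 else np.nan

    coefficients = pd.DataFrame(
        {"coef": coef, "se": res.bse, "p": res.pvalues}, index=names
    )

    return CosinorFit(
        mesor=float(coef["const"]),
        amplitude=amplitude,
        acrophase=acrophase,
        se_amplitude=se_amp,
        se_acrophase=se_phi,
        beta=beta,
        gamma=gamma,
        cov_bg=Vbg,
        period=period,
        p_sinusoid=p_sin,
        eta2_sinusoid=eta2_terms.get("sinusoid", np.nan),
        coefficients=coefficients,
        eta2_terms=eta2_terms,
        boxcox_lambda=lam,
        n=len(y),
        response=response,
        design=design,
        sigma2=float(res.mse_resid),
        rss=rss_full,
        ss_total=ss_total,
        thermal_col=thermal_col,
    )


def reference_mesor(fit: CosinorFit) -> float:
    """Mesor at reference covariate levels with numeric covariates at their means."""
    m = fit.mesor
    coefs = fit.coefficients["coef"]
    for cov, mean in fit.design.numeric_means.items():
        if cov in coefs.index:
            m += coefs[cov] * mean
    return float(m)


def cosinor_predict(
    fit: CosinorFit,
    times,
    include: str = "sinusoid",
    thermal_values=None,
) -> np.ndarray:
    """Predict the response at reference covariate levels.

    ``include``:
      * ``"sinusoid"`` — mesor + fitted sinusoid (categoricals at reference,
        numeric covariates at their sample means);
      * ``"thermal"`` — mesor + thermal term applied to ``thermal_values``
        (centered at the fitting sample's mean);
      * ``"full"`` — mesor + sinusoid + thermal.
    """
    times = np.asarray(times, dtype=float)
    omega = 2 * np.pi / fit.period
    m = reference_mesor(fit)
    pred = np.full(times.shape, m)
    if include in ("sinusoid", "full"):
        pred = pred + fit.beta * np.cos(omega * times) + fit.gamma * np.sin(omega * times)
    if include in ("thermal", "full"):
        if fit.thermal_col is None:
            raise ValueError("fit has no thermal term; cannot make a thermal prediction")
        if thermal_values is None:
            raise ValueError("thermal prediction requires thermal_values at the times")
        coefs = fit.coefficients["coef"]
        centered = np.asarray(thermal_values, dtype=float) - fit.design.numeric_means[
            fit.thermal_col
        ]
        # reference_mesor already placed the thermal covariate at its mean
        pred = pred + coefs[fit.thermal_col] * centered
    if include not in ("sinusoid", "thermal", "full"):
        raise ValueError(f"unknown include mode {include!r}")
    return pred


def sinusoid_anova(fit: CosinorFit) -> dict:
    """Joint sinusoid F-test and classical (Type II) eta^2 per model term."""
    if fit.n - len(fit.coefficients) < 2:
        raise ValueError("saturated model: fewer than 2 residual degrees of freedom")
    return {
        "p_sinusoid": fit.p_sinusoid,
        "eta2_sinusoid": fit.eta2_sinusoid,
        "eta2_terms": dict(fit.eta2_terms),
    }
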