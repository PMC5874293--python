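"""Circular summaries of acrophases across site x year cosinor fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cosinor import wrap_phase

_RESULTANT_TOL = 1e-12


@dataclass
class CircularMean:
    mean_direction: float       # radians in (-pi, pi]; nan when undefined
    resultant_length: float     # in [0, 1]
    defined: bool               # False for antipodal/zero-resultant input


def circular_mean(phases, weights=None) -> CircularMean:
    """Weighted vector mean of angles on the unit circle.

    mean_direction = atan2(sum w sin phi, sum w cos phi), wrapped to
    (-pi, pi]; resultant length R = |sum w e^{i phi}| / sum w. When the
    resultant cancels (e.g. antipodal phases with equal weight) the
    direction is undefined and flagged rather than returned as an
    arbitrary angle.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one phase")
    if weights is None:
        w = np.ones_like(phases)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != phases.shape:
            raise ValueError("weights must match phases in shape")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("weights sum to zero")
    C = float(np.sum(w * np.cos(phases)))
    S = float(np.sum(w * np.sin(phases)))
    R = float(np.hypot(C, S) / wsum)
    if R < _RESULTANT_TOL:
        return CircularMean(mean_direction=float("nan"), resultant_length=0.0, defined=False)
    return CircularMean(
        mean_direction=wrap_phase(np.arctan2(S, C)),
        resultant_length=min(R, 1.0),
        defined=True,
    )


@dataclass
class PeakTiming:
    months_after_origin: float
    calendar_month: float       # 1.0 = January 1st boundary, wraps mod 12


def phase_to_month(phi: float, period: float = 12.0, origin_month: int = 10) -> PeakTiming:
    """Render an acrophase as peak timing: t* = (-phi * period) / (2 pi) mod period.

    ``origin_month`` is the calendar month (1-12) at which t = 0 sits; the
    default of 10 corresponds to an October study start.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    t_star = float((-phi * period / (2 * np.pi)) % period)
    cal = 1.0 + (origin_month - 1 + t_star) % 12.0
    return PeakTiming(months_after_origin=t_star, calendar_month=cal)


def acrophase_summary(records: pd.DataFrame, weight_col: str = "eta2") -> pd.DataFrame:
    """Per-gene circular mean direction and resultant length across fits.

    ``records`` needs columns gene, site, year, acrophase and (optionally)
    a weight column (effect-size weighting mirrors bubble-sized acrophase
    plots). Both the weighted and unweighted summaries are emitted.
    """
    rows = []
    for gene, sub in records.groupby("gene", observed=True):
        phases = sub["acrophase"].to_numpy(dtype=float)
        unw = circular_mean(phases)
        if weight_col in sub.columns and sub[weight_col].notna().all():
            wtd = circular_mean(phases, sub[weight_col].to_numpy(dtype=float))
        else:
            wtd = unw
        rows.append(
            {
                "gene": gene,
                "n_fits": len(sub),
                "mean_direction": wtd.mean_direction,
                "resultant_length": wtd.resultant_length,
                "direction_defined": wtd.defined,
                "mean_direction_unweighted": unw.mean_direction,
                "resultant_length_unweighted": unw.resultant_length,
            }
        )
    return pd.DataFrame(rows)
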