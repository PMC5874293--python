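"""Domain types and readers for expression tables and temperature logs.

The package works on two kinds of input: per-fish relative gene expression
(RE) tables carrying design covariates, and habitat/tank water-temperature
logger series. Time is expressed in decimal months since a study origin so
that a 12-month period maps onto one tropical year.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Days per month so that 12 months equal one tropical year (365.25 d).
DAYS_PER_MONTH = 365.25 / 12.0

#: Columns every expression table must carry.
REQUIRED_COLUMNS = ("fish_id", "site", "sample_time", "sex", "length_mm", "plate_id")

#: Optional treatment/design factors recognised by the readers.
OPTIONAL_FACTORS = ("heat_treatment", "ration", "temp_group", "pp_group", "tank_id", "year")


class FormatError(ValueError):
    """Raised when an input file violates the expression/temperature contract."""


@dataclass
class ExpressionTable:
    """Per-fish expression table: design covariates plus RE values per gene.

    RE columns are named ``re_<gene>``; values are strictly positive (the
    log10 and Box-Cox transforms downstream require it). ``t_months`` is
    decimal months since ``origin``.
    """

    df: pd.DataFrame
    genes: tuple[str, ...]
    origin: pd.Timestamp | None = None

    @property
    def n(self) -> int:
        return len(self.df)

    def re_column(self, gene: str) -> pd.Series:
        col = f"re_{gene}"
        if col not in self.df.columns:
            raise KeyError(f"gene {gene!r} not present in table (no column {col})")
        return self.df[col]

    def with_time_coordinate(self, origin: pd.Timestamp) -> "ExpressionTable":
        """Return a copy with ``t_months`` computed relative to ``origin``."""
        df = self.df.copy()
        df["t_months"] = to_decimal_months(df["sample_time"], origin)
        return ExpressionTable(df=df, genes=self.genes, origin=pd.Timestamp(origin))


@dataclass
class TemperatureSeries:
    """Timestamped water-temperature readings for one habitat or tank."""

    site_or_tank: str
    timestamps: pd.DatetimeIndex
    temps_c: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temps_c = np.asarray(self.temps_c, dtype=float)
        if len(self.timestamps) != len(self.temps_c):
            raise ValueError("timestamps and temps_c must have equal length")
        if len(self.timestamps) > 1:
            diffs = np.diff(self.timestamps.asi8)
            if np.any(diffs <= 0):
                i = int(np.argmax(diffs <= 0))
                if diffs[i] == 0:
                    raise FormatError(
                        f"duplicated timestamp {self.timestamps[i + 1]} in series "
                        f"{self.site_or_tank!r}"
                    )
                raise FormatError(
                    f"timestamps not strictly increasing at {self.timestamps[i + 1]}"
                )
        if not np.all(np.isfinite(self.temps_c)):
            raise FormatError(f"non-finite temperature in series {self.site_or_tank!r}")

    @property
    def median_gap(self) -> pd.Timedelta:
        if len(self.timestamps) < 2:
            return pd.Timedelta(0)
        return pd.Timedelta(np.median(np.diff(self.timestamps.asi8)), unit="ns")

    def as_series(self) -> pd.Series:
        return pd.Series(self.temps_c, index=self.timestamps, name=self.site_or_tank)


@dataclass
class GenePolarity:
    """Map gene -> -1 (winter-biased) / +1 (summer-biased)."""

    polarity: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.polarity.items() if v not in (-1, 1)}
        if bad:
            raise ValueError(f"polarity values must be -1 or +1, got {bad}")

    def __getitem__(self, gene: str) -> int:
        return self.polarity[gene]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.polarity)

    @classmethod
    def read_csv(cls, path) -> "GenePolarity":
        df = pd.read_csv(path)
        if not {"gene", "polarity"} <= set(df.columns):
            raise FormatError("polarity CSV needs columns gene,polarity")
        return cls(dict(zip(df["gene"], df["polarity"].astype(int))))

    def write_csv(self, path) -> None:
        pd.DataFrame(
            {"gene": list(self.polarity), "polarity": list(self.polarity.values())}
        ).to_csv(path, index=False)


def to_decimal_months(sample_time, origin) -> np.ndarray | float:
    """Decimal months since ``origin``: (sample_time - origin) / 30.4375 days.

    One month is fixed at 365.25/12 days so that a period of 12 months
    equals one tropical year.
    """
    t = pd.to_datetime(sample_time)
    origin = pd.Timestamp(origin)
    if isinstance(t, pd.Timestamp):
        return (t - origin).total_seconds() / (DAYS_PER_MONTH * 86400.0)
    delta = (pd.DatetimeIndex(t) - origin).total_seconds()
    return np.asarray(delta) / (DAYS_PER_MONTH * 86400.0)


def read_expression_table(path, gene_list, origin=None) -> ExpressionTable:
    """Read a per-fish expression CSV, validating the schema and positivity.

    Rows missing sex or length, or with a non-positive RE value, are
    rejected (and counted in a log message): every downstream model adjusts
    for sex and length, and RE must be strictly positive for log10/Box-Cox.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"expression CSV missing required columns: {missing}")
    re_cols = [f"re_{g}" for g in gene_list]
    missing_genes = [c for c in re_cols if c not in df.columns]
    if missing_genes:
        raise FormatError(f"expression CSV missing RE columns: {missing_genes}")

    try:
        df["sample_time"] = pd.to_datetime(df["sample_time"], utc=True).dt.tz_localize(None)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable sample_time: {exc}") from exc

    if df.empty:
        warnings.warn("expression CSV contains a header but no rows", stacklevel=2)
        return ExpressionTable(df=df, genes=tuple(gene_list))

    n0 = len(df)
    keep = df["sex"].notna() & df["length_mm"].notna() & (df["length_mm"] > 0)
    for c in re_cols:
        keep &= df[c].notna() & (df[c] > 0)
    rejected = int(n0 - keep.sum())
    if rejected:
        logger.warning("rejected %d/%d rows (missing sex/length or non-positive RE)", rejected, n0)
    df = df.loc[keep].reset_index(drop=True)
    for c in ("site", "sex", "plate_id", *[f for f in OPTIONAL_FACTORS if f in df.columns]):
        df[c] = df[c].astype("category")
    table = ExpressionTable(df=df, genes=tuple(gene_list))
    if origin is not None:
        table = table.with_time_coordinate(origin)
    return table


def write_expression_table(table: ExpressionTable, path) -> None:
    df = table.df.copy()
    df["sample_time"] = df["sample_time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_temperature_log(path, site_or_tank: str | None = None) -> TemperatureSeries:
    """Read a ``timestamp,temp_c`` CSV into a sorted, validated series."""
    df = pd.read_csv(path)
    if not {"timestamp", "temp_c"} <= set(df.columns):
        raise FormatError("temperature CSV needs columns timestamp,temp_c")
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    except (ValueError, TypeError) as exc:
        # pandas reports the offending value; find its line for the message
        bad_line = None
        for i, v in enumerate(df["timestamp"]):
            try:
                pd.Timestamp(v)
            except (ValueError, TypeError):
                bad_line = i + 2  # 1-based + header
                break
        raise FormatError(f"unparseable timestamp at line {bad_line}: {exc}") from exc
    if not ts.is_monotonic_increasing:
        warnings.warn("temperature log not sorted; sorting by timestamp", stacklevel=2)
        order = np.argsort(ts.values, kind="stable")
        ts = ts.iloc[order].reset_index(drop=True)
        df = df.iloc[order].reset_index(drop=True)
    dup = ts.duplicated()
    if dup.any():
        raise FormatError(f"duplicated timestamp {ts[dup].iloc[0]} in temperature log")
    series = TemperatureSeries(
        site_or_tank=site_or_tank or str(path),
        timestamps=pd.DatetimeIndex(ts),
        temps_c=df["temp_c"].to_numpy(dtype=float),
    )
    if len(series.timestamps) > 1 and series.median_gap > pd.Timedelta(minutes=10):
        warnings.warn(
            f"median inter-reading gap {series.median_gap} exceeds 10 min; "
            "input may not be logger-grade",
            stacklevel=2,
        )
    return series


def write_temperature_log(series: TemperatureSeries, path) -> None:
    pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "temp_c": series.temps_c,
        }
    ).to_csv(path, index=False)


def mean_prior_week_temp(series: TemperatureSeries, sample_time) -> float:
    """Mean temperature over the half-open week [t - 7 d, t) before ``sample_time``."""
    return float(mean_prior_week_temps(series, [sample_time])[0])


def mean_prior_week_temps(series: TemperatureSeries, sample_times) -> np.ndarray:
    """Vectorised prior-week means for many sampling instants.

    The window is half-open: readings at exactly ``sample_time`` are
    excluded. Errors if the series does not cover a requested window.
    """
    times = pd.DatetimeIndex(pd.to_datetime(sample_times))
    ts = series.timestamps.asi8
    temps = series.temps_c
    week = pd.Timedelta(days=7)
    lo = (times - week).asi8
    hi = times.asi8
    gap = max(series.median_gap, pd.Timedelta(minutes=1))
    out = np.empty(len(times))
    csum = np.concatenate([[0.0], np.cumsum(temps)])
    i0 = np.searchsorted(ts, lo, side="left")
    i1 = np.searchsorted(ts, hi, side="left")
    for j in range(len(times)):
        if lo[j] < ts[0] or hi[j] > ts[-1] + 2 * gap.value:
            raise ValueError(
                f"temperature series {series.site_or_tank!r} does not cover the "
                f"prior-week window [{pd.Timestamp(lo[j])}, {pd.Timestamp(hi[j])}); "
                f"series spans [{series.timestamps[0]}, {series.timestamps[-1]}]"
            )
        if i1[j] <= i0[j]:
            raise ValueError(
                f"no readings in prior-week window ending {pd.Timestamp(hi[j])}"
            )
        out[j] = (csum[i1[j]] - csum[i0[j]]) / (i1[j] - i0[j])
    return out
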