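"""Seasonal reporter index (SRI): a signed sum of standardized log10 RE values.

Each gene's relative expression is log10-transformed and z-scored within a
standardization batch (default: site x study-year, matching assays that are
only on a common scale within a study iteration); the z-scores are then
summed with winter-biased genes entering negatively and summer-biased genes
positively. High SRI = summer-like expression profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionTable, GenePolarity


@dataclass
class SriResult:
    """Per-fish SRI plus the standardization constants that produced it."""

    sri: pd.Series                     # indexed like the input table rows
    constants: pd.DataFrame            # columns: batch keys..., gene, mean, sd
    polarity: GenePolarity
    batch_key: tuple[str, ...]

    def attach(self, table: ExpressionTable, column: str = "sri") -> ExpressionTable:
        """Return a copy of ``table`` with the SRI as an extra column."""
        df = table.df.copy()
        df[column] = self.sri.values
        return ExpressionTable(df=df, genes=table.genes, origin=table.origin)


def compute_sri(
    table: ExpressionTable,
    polarity: GenePolarity,
    batch_key: tuple[str, ...] | list[str] | None = ("site", "year"),
) -> SriResult:
    """Compute the SRI for every fish in ``table``.

    Parameters
    ----------
    table
        Expression table containing an ``re_<gene>`` column for every gene
        in ``polarity``; all RE values must be > 0.
    polarity
        Gene -> {-1, +1} map (winter-biased negative, summer-biased positive).
    batch_key
        Columns defining standardization batches. Defaults to site x year;
        keys absent from the table are dropped (so a single-site table
        standardizes within year only, etc.). ``None`` or empty means one
        global batch.

    Standardization uses the sample (n-1) standard deviation. A gene whose
    log10 RE has zero variance within a batch is an error: silently
    dropping it would change the index definition.
    """
    df = table.df
    genes = polarity.genes
    missing = [g for g in genes if f"re_{g}" not in df.columns]
    if missing:
        raise KeyError(f"polarity genes missing from table: {missing}")

    keys = [k for k in (batch_key or ()) if k in df.columns]
    if keys:
        groups = df.groupby(keys, observed=True).indices
    else:
        groups = {(): np.arange(len(df))}

    sri = np.zeros(len(df))
    const_rows = []
    for batch, idx in groups.items():
        batch = batch if isinstance(batch, tuple) else (batch,)
        for g in genes:
            vals = df[f"re_{g}"].to_numpy(dtype=float)[idx]
            if np.any(vals <= 0):
                raise ValueError(f"non-positive RE for gene {g!r}; cannot log10")
            logv = np.log10(vals)
            mu = logv.mean()
            sd = logv.std(ddof=1) if len(logv) > 1 else 0.0
            if sd == 0.0 or not np.isfinite(sd):
                raise ValueError(
                    f"zero variance gene {g!r} in batch {dict(zip(keys, batch))}"
                )
            sri[idx] += polarity[g] * (logv - mu) / sd
            const_rows.append({**dict(zip(keys, batch)), "gene": g, "mean": mu, "sd": sd})

    return SriResult(
        sri=pd.Series(sri, index=df.index, name="sri"),
        constants=pd.DataFrame(const_rows),
        polarity=polarity,
        batch_key=tuple(keys),
    )
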