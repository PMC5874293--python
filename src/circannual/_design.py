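"""Design-matrix construction shared by the regression modules.

Categorical covariates are dummy-coded against a reference (first) level;
numeric covariates enter untouched. Terms remember which design columns
they own so joint F-tests and Type II sums of squares can be computed per
term rather than per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg


@dataclass
class DesignInfo:
    """A named design matrix plus the column span of each model term."""

    matrix: pd.DataFrame
    terms: dict[str, list[str]] = field(default_factory=dict)
    numeric_means: dict[str, float] = field(default_factory=dict)
    reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    def term_columns(self, term: str) -> list[str]:
        return self.terms[term]


def is_categorical(s: pd.Series) -> bool:
    return isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object or s.dtype == bool


def build_design(
    df: pd.DataFrame,
    covariates: list[str] | tuple[str, ...],
    add_intercept: bool = True,
) -> DesignInfo:
    """Dummy-code ``covariates`` from ``df`` into a named design matrix."""
    cols: dict[str, np.ndarray] = {}
    terms: dict[str, list[str]] = {}
    numeric_means: dict[str, float] = {}
    reference: dict[str, str] = {}
    if add_intercept:
        cols["const"] = np.ones(len(df))
        terms["const"] = ["const"]
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate {cov!r} not in table")
        s = df[cov]
        if is_categorical(s):
            cat = s.astype("category")
            levels = [lv for lv in cat.cat.categories if (cat == lv).any()]
            if len(levels) < 1:
                raise ValueError(f"covariate {cov!r} has no observed levels")
            reference[cov] = str(levels[0])
            names = []
            for lv in levels[1:]:
                name = f"{cov}[{lv}]"
                cols[name] = (cat == lv).to_numpy(dtype=float)
                names.append(name)
            terms[cov] = names
        else:
            vals = s.to_numpy(dtype=float)
            numeric_means[cov] = float(np.mean(vals))
            cols[cov] = vals
            terms[cov] = [cov]
    matrix = pd.DataFrame(cols, index=df.index)
    return DesignInfo(matrix=matrix, terms=terms, numeric_means=numeric_means,
                      reference_levels=reference)


def check_full_rank(X: pd.DataFrame) -> None:
    """Raise if the design is rank deficient, naming the aliased columns."""
    arr = X.to_numpy(dtype=float)
    r = np.linalg.matrix_rank(arr)
    if r < arr.shape[1]:
        _, R, piv = linalg.qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[p] for p in piv[len(diag):]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
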