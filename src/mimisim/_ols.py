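"""Shared least-squares machinery: design-matrix hygiene and OLS wrapper.

All analysis and imputation models in this package are ordinary linear
models, fitted with statsmodels. Structural aliasing is expected in some
cells (e.g. the confounder is constant among complete rows when missingness
is deterministic, or the missing-data indicator is constant when a replicate
has no missing values), so designs are reduced to a maximal linearly
independent set of columns before fitting, keeping earlier columns in
preference to later ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["FitFailure", "drop_aliased", "OLSFit", "fit_ols"]

_RANK_RTOL = 1e-9


class FitFailure(RuntimeError):
    """A model fit could not be completed (too few rows, empty design...)."""


def drop_aliased(X: pd.DataFrame) -> Tuple[pd.DataFrame, List[str]]:
    """Reduce a design matrix to linearly independent columns.

    Columns are scanned left to right; a column is kept only if it increases
    the rank of the running design, so earlier columns take precedence.
    Returns the reduced design and the names of the dropped columns.
    """
    arr = X.to_numpy(dtype=float)
    kept: List[int] = []
    dropped: List[str] = []
    rank = 0
    for j in range(arr.shape[1]):
        cand = arr[:, kept + [j]]
        new_rank = np.linalg.matrix_rank(cand, tol=_RANK_RTOL * np.abs(cand).max())
        if new_rank > rank:
            kept.append(j)
            rank = new_rank
        else:
            dropped.append(X.columns[j])
    return X.iloc[:, kept], dropped


@dataclass
class OLSFit:
    """Least-squares fit with the pieces downstream consumers need."""

    params: pd.Series
    bse: pd.Series
    df_resid: int
    nobs: int
    ssr: float
    normalized_cov: pd.DataFrame  # (X'X)^{-1}
    dropped: Tuple[str, ...]

    @property
    def resid_var(self) -> float:
        if self.df_resid <= 0:
            return 0.0
        return self.ssr / self.df_resid


def fit_ols(y: np.ndarray, X: pd.DataFrame, min_extra_rows: int = 2) -> OLSFit:
    """OLS of ``y`` on ``X`` after alias reduction.

    Raises :class:`FitFailure` when fewer than ``k + min_extra_rows`` rows
    are available for ``k`` retained predictors.
    """
    if len(y) != len(X):
        raise ValueError("y and X must have the same number of rows")
    X_kept, dropped = drop_aliased(X)
    k = X_kept.shape[1]
    if k == 0:
        raise FitFailure("design matrix has no independent columns")
    if len(y) < k + min_extra_rows:
        raise FitFailure(
            f"too few rows ({len(y)}) for {k} predictors"
        )
    res = sm.OLS(np.asarray(y, dtype=float), X_kept.to_numpy(dtype=float)).fit()
    names = list(X_kept.columns)
    return OLSFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        ssr=float(res.ssr),
        normalized_cov=pd.DataFrame(
            res.normalized_cov_params, index=names, columns=names
        ),
        dropped=tuple(dropped),
    )
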