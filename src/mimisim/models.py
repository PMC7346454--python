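"""Analysis models and Rubin's-rules pooling.

Five analysis strategies are compared, each as an ordinary linear outcome
model, with and without the confounder ``U`` in the design:

* ``CC`` — complete case: fit only rows with the exposure observed.
* ``MI_A`` — standard multiple imputation: outcome on the imputed exposure.
* ``MI_RplusA`` — imputation plus a missing-indicator main effect
  ``(1 - R_A)``.
* ``MI_RtimesA`` — imputation plus the indicator and its interaction with
  the imputed exposure.
* ``Completed`` — the benchmark fit on the fully observed exposure.

Coefficient names are canonical across models — ``A`` for the exposure,
``R`` for the missing-indicator main effect, ``RA`` for its interaction
with the exposure, ``U``/``UA`` for the confounder terms — so summaries can
align the same estimand across strategies. Multiply-imputed fits are pooled
by Rubin's rules with Barnard–Rubin adjusted degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import FitFailure, fit_ols
from .dgm import SimDataset
from .imputation import CompletedDataset

__all__ = [
    "FitResult",
    "PooledResult",
    "fit_complete_case",
    "fit_outcome_model",
    "fit_completed_data",
    "pool_rubin",
    "FitFailure",
    "MI_MODELS",
    "ALL_METHODS",
]

MI_A = "MI_A"
MI_RPLUSA = "MI_RplusA"
MI_RTIMESA = "MI_RtimesA"
MI_MODELS: Tuple[str, ...] = (MI_A, MI_RPLUSA, MI_RTIMESA)
ALL_METHODS: Tuple[str, ...] = ("CC",) + MI_MODELS + ("Completed",)


@dataclass
class FitResult:
    """One fitted outcome model: estimates, SEs, residual df.

    Confidence intervals use the t distribution on the residual degrees of
    freedom.
    """

    method: str
    u_observed: bool
    params: pd.Series
    se: pd.Series
    df_resid: int
    nobs: int
    dropped: Tuple[str, ...] = ()

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        half = stats.t.ppf(1 - alpha / 2, self.df_resid) * self.se
        return pd.DataFrame(
            {"ci_lower": self.params - half, "ci_upper": self.params + half}
        )

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "df": float(self.df_resid),
                "ci_lower": ci["ci_lower"],
                "ci_upper": ci["ci_upper"],
            }
        )


@dataclass
class PooledResult:
    """Rubin's-rules combination of ``m`` imputed-data fits.

    Per coefficient: pooled estimate (mean over imputations), within- and
    between-imputation variances ``W`` and ``B``, total variance
    ``T = W + (1 + 1/m) B``, and a t interval on Barnard–Rubin adjusted
    degrees of freedom.
    """

    method: str
    u_observed: bool
    m: int
    table: pd.DataFrame  # index: coefficient; estimate, W, B, T, se, df, ci
    flags: Tuple[str, ...] = ()

    @property
    def params(self) -> pd.Series:
        return self.table["estimate"]

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:  # alpha fixed at pool time
        return self.table[["estimate", "se", "df", "ci_lower", "ci_upper"]]


def _outcome_design(
    frame: pd.DataFrame, exposure: np.ndarray, method: str, u_observed: bool
) -> pd.DataFrame:
    n = len(frame)
    cols: Dict[str, np.ndarray] = {"intercept": np.ones(n), "A": exposure}
    if method in (MI_RPLUSA, MI_RTIMESA):
        cols["R"] = 1.0 - frame["R_A"].to_numpy(dtype=float)
    if method == MI_RTIMESA:
        cols["RA"] = exposure * (1.0 - frame["R_A"].to_numpy(dtype=float))
    if u_observed:
        u = frame["U"].to_numpy(dtype=float)
        cols["U"] = u
        cols["UA"] = u * exposure
    return pd.DataFrame(cols, index=frame.index)


def _fit(frame, exposure, method, u_observed) -> FitResult:
    X = _outcome_design(frame, exposure, method, u_observed)
    fit = fit_ols(frame["Y"].to_numpy(), X, min_extra_rows=2)
    return FitResult(
        method=method,
        u_observed=u_observed,
        params=fit.params,
        se=fit.bse,
        df_resid=fit.df_resid,
        nobs=fit.nobs,
        dropped=fit.dropped,
    )


def fit_complete_case(dataset: SimDataset, u_observed: bool = False) -> FitResult:
    """OLS of the outcome on the observed exposure among complete rows."""
    obs = dataset.frame[dataset.frame["R_A"] == 1]
    if len(obs) == 0:
        raise FitFailure("no complete rows for complete-case analysis")
    res = _fit(obs, obs["A_star"].to_numpy(), "CC", u_observed)
    return res


def fit_outcome_model(
    completed: CompletedDataset, method: str, u_observed: bool = False
) -> FitResult:
    """OLS of the outcome on an imputed-exposure design.

    ``method`` selects the design: the imputed exposure alone (``MI_A``),
    plus the missing-indicator main effect (``MI_RplusA``), plus also the
    indicator-exposure interaction (``MI_RtimesA``). When a replicate has
    no missing rows the indicator columns are constant and are dropped
    (recorded on the result), so the richer models collapse to ``MI_A``.
    """
    if method not in MI_MODELS:
        raise ValueError(f"unknown outcome model {method!r}")
    frame = completed.frame
    if frame["A_imp"].isna().any():
        raise ValueError("completed dataset has missing A_imp values")
    return _fit(frame, frame["A_imp"].to_numpy(), method, u_observed)


def fit_completed_data(dataset: SimDataset, u_observed: bool = False) -> FitResult:
    """Benchmark OLS on the full, unmasked exposure."""
    res = _fit(dataset.frame, dataset.frame["A"].to_numpy(), "Completed", u_observed)
    return res


def _barnard_rubin_df(m: int, lam: float, nu_com: float) -> float:
    """Adjusted degrees of freedom for the pooled t interval.

    ``lam`` is the fraction of total variance due to missingness; the
    adjusted df harmonically combines the classical large-sample df with an
    observed-data df that cannot exceed the complete-data df.
    """
    nu_old = (m - 1) / lam**2
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    return 1.0 / (1.0 / nu_old + 1.0 / nu_obs)


def pool_rubin(fits: Sequence[FitResult], alpha: float = 0.05) -> PooledResult:
    """Combine per-imputation fits by Rubin's rules.

    Requires a non-empty list of fits with identical coefficient sets
    (alias reconciliation happens upstream; a mismatch here is a hard
    error). With a single fit the between-imputation variance is undefined:
    the total variance falls back to the within variance and the result is
    flagged ``single_imputation``.
    """
    if len(fits) == 0:
        raise ValueError("pool_rubin requires at least one fit")
    names = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != names:
            raise ValueError(
                "inconsistent coefficient sets across imputations: "
                f"{names} vs {list(f.params.index)}"
            )
    m = len(fits)
    est = np.vstack([f.params.to_numpy() for f in fits])
    ses = np.vstack([f.se.to_numpy() for f in fits])
    qbar = est.mean(axis=0)
    W = (ses**2).mean(axis=0)
    flags: List[str] = []
    if m == 1:
        B = np.zeros_like(qbar)
        flags.append("single_imputation")
    else:
        B = est.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    nu_com = float(min(f.df_resid for f in fits))
    dfs = np.empty_like(qbar)
    for j in range(len(qbar)):
        if T[j] <= 0 or B[j] <= 0 or m == 1:
            dfs[j] = nu_com
        else:
            lam = (1.0 + 1.0 / m) * B[j] / T[j]
            dfs[j] = _barnard_rubin_df(m, lam, nu_com)
    se = np.sqrt(T)
    half = stats.t.ppf(1 - alpha / 2, dfs) * se
    table = pd.DataFrame(
        {
            "estimate": qbar,
            "W": W,
            "B": B,
            "T": T,
            "se": se,
            "df": dfs,
            "ci_lower": qbar - half,
            "ci_upper": qbar + half,
        },
        index=names,
    )
    return PooledResult(
        method=fits[0].method,
        u_observed=fits[0].u_observed,
        m=m,
        table=table,
        flags=tuple(flags),
    )
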