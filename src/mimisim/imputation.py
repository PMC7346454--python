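"""Proper multiple imputation of the incomplete exposure.

A single variable (the exposure ``A``) is incomplete, so the joint-normal
imputation model reduces to a linear regression of ``A`` on the outcome —
plus the confounder and its interaction with the outcome when the
confounder is measured. "Proper" imputation follows the standard Bayesian
construction under the noninformative prior: for each of the ``m``
imputations, draw the residual variance from its scaled inverse-chi-square
posterior, draw the coefficients from a normal centred at the least-squares
estimates with covariance scaled by that variance, then draw each missing
exposure value from the implied normal predictive distribution. The
between-imputation spread therefore reflects estimation uncertainty as well
as residual noise, which is what Rubin's variance rules require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from ._ols import FitFailure, OLSFit, fit_ols
from .dgm import ScenarioConfig, SeedLike, SimDataset, as_rng

__all__ = [
    "ImputationModelSpec",
    "CompletedDataset",
    "fit_imputation_model",
    "draw_proper_imputations",
    "FitFailure",
]


@dataclass(frozen=True)
class ImputationModelSpec:
    """Predictor set and imputation count for the exposure imputation model.

    With the confounder hidden the predictors are ``{Y}``; with the
    confounder observed they are ``{Y, U, U*Y}`` — the interaction is always
    included so the imputation model is at least as rich as the analysis
    models it feeds.
    """

    u_observed: bool = False
    m: int = 5

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("number of imputations m must be >= 1")

    @property
    def predictors(self) -> Tuple[str, ...]:
        if self.u_observed:
            return ("Y", "U", "UY")
        return ("Y",)


@dataclass
class CompletedDataset:
    """One imputed copy of a simulated dataset.

    ``frame`` carries the original columns plus ``A_imp``: equal to the
    observed exposure where present, a drawn value where it was missing.
    Observed entries are never altered.
    """

    frame: pd.DataFrame
    config: ScenarioConfig
    imputation_index: int
    dropped_predictors: Tuple[str, ...] = ()


def _design(frame: pd.DataFrame, spec: ImputationModelSpec) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(frame))}
    cols["Y"] = frame["Y"].to_numpy()
    if spec.u_observed:
        cols["U"] = frame["U"].to_numpy(dtype=float)
        cols["UY"] = cols["U"] * cols["Y"]
    return pd.DataFrame(cols, index=frame.index)


def fit_imputation_model(dataset: SimDataset, spec: ImputationModelSpec) -> OLSFit:
    """Least-squares fit of the imputation model on the complete rows.

    Structurally aliased predictors (e.g. the confounder when it is constant
    among complete rows under deterministic missingness) are dropped and
    recorded on the returned fit.
    """
    obs = dataset.frame[dataset.frame["R_A"] == 1]
    if len(obs) == 0:
        raise FitFailure("no observed exposure values to fit the imputation model")
    X = _design(obs, spec)
    y = obs["A_star"].to_numpy()
    return fit_ols(y, X, min_extra_rows=2)


def draw_proper_imputations(
    dataset: SimDataset, spec: ImputationModelSpec, seed: SeedLike
) -> List[CompletedDataset]:
    """Draw ``spec.m`` completed datasets by proper imputation.

    Per imputation: residual variance from ``df * s^2 / chi2(df)``,
    coefficients from ``N(phi_hat, sigma2 * (X'X)^{-1})``, missing values
    from ``N(x'phi, sigma2)``. A zero residual variance (exact linear
    relation) degenerates to the deterministic prediction. Reproducible
    from ``seed``.
    """
    rng = as_rng(seed)
    fit = fit_imputation_model(dataset, spec)
    frame = dataset.frame
    miss_mask = (frame["R_A"] == 0).to_numpy()
    X_miss = _design(frame.loc[miss_mask], spec)[list(fit.params.index)].to_numpy(
        dtype=float
    )
    xtx_inv = fit.normalized_cov.to_numpy()
    # guard tiny negative eigenvalues from round-off
    try:
        chol = np.linalg.cholesky(xtx_inv)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(xtx_inv)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    phi_hat = fit.params.to_numpy()
    k = len(phi_hat)
    out: List[CompletedDataset] = []
    for j in range(spec.m):
        if fit.df_resid > 0 and fit.resid_var > 0:
            sigma2 = fit.ssr / rng.chisquare(fit.df_resid)
        else:
            sigma2 = 0.0
        if sigma2 > 0:
            phi = phi_hat + np.sqrt(sigma2) * (chol @ rng.standard_normal(k))
        else:
            phi = phi_hat
        a_imp = frame["A_star"].to_numpy().copy()
        if miss_mask.any():
            mu = X_miss @ phi
            a_imp[miss_mask] = mu + np.sqrt(sigma2) * rng.standard_normal(
                miss_mask.sum()
            )
        completed = frame.copy()
        completed["A_imp"] = a_imp
        out.append(
            CompletedDataset(
                frame=completed,
                config=dataset.config,
                imputation_index=j,
                dropped_predictors=fit.dropped,
            )
        )
    return out
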