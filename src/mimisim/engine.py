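"""Factorial grid enumeration, replicate execution and summaries.

The study is a fully factorial Monte Carlo design. The logistic-missingness
stratum crosses the exposure-confounder effect, the three logistic slopes,
the outcome-confounder effect and interaction, the outcome SD and the
target missingness proportion (11,520 cells); the deterministic
``R_A = 1 - U`` stratum drops the redundant slopes and instead varies the
confounder prevalence, which there controls missingness (288 cells).

Seeding is counter-based: the stream for replicate ``r`` of cell ``c`` is
``SeedSequence([study_seed, c, r, stage])``, so results are identical under
any execution order or degree of parallelism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dgm import DETERMINISTIC, LOGISTIC, ScenarioConfig, generate_dataset
from .imputation import ImputationModelSpec, draw_proper_imputations
from .models import (
    ALL_METHODS,
    MI_MODELS,
    FitFailure,
    fit_complete_case,
    fit_completed_data,
    fit_outcome_model,
    pool_rubin,
)

__all__ = [
    "GridSpec",
    "CellResult",
    "enumerate_grid",
    "run_replicate",
    "run_cell",
    "run_grid",
    "coverage",
    "summarize_estimates",
    "tidy_summary",
]

PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass(frozen=True)
class GridSpec:
    """Parameter grids of the factorial design (defaults: the full study).

    ``gamma_A``, ``sigma_A``, ``n`` and (logistic stratum) ``pi_U`` are held
    fixed; intercepts are solved per cell. The deterministic stratum varies
    ``pi_U`` instead of the logistic slopes and missingness target.
    """

    alpha_U_grid: Tuple[float, ...] = (0.0, 0.1, 0.5, 1.0)
    beta_A_grid: Tuple[float, ...] = (0.0, 0.1, 0.5, 1.0)
    gamma_U_grid: Tuple[float, ...] = (0.0, 0.1, 0.5, 1.0)
    beta_U_grid: Tuple[float, ...] = (-1.0, 0.0, 0.1, 0.5, 1.0)
    beta_UA_grid: Tuple[float, ...] = (0.0, 0.5)
    gamma_UA_grid: Tuple[float, ...] = (0.0, 0.5)
    sigma_Y_grid: Tuple[float, ...] = (0.1, 0.5, 1.0)
    p_missing_grid: Tuple[float, ...] = (0.25, 0.5, 0.75)
    det_pi_U_grid: Tuple[float, ...] = (0.25, 0.5, 0.75)
    gamma_A: float = 1.0
    sigma_A: float = 1.0
    pi_U: float = 0.5
    n: int = 10_000
    replicates: int = 200
    include_deterministic: bool = True

    @property
    def n_logistic(self) -> int:
        return (
            len(self.alpha_U_grid)
            * len(self.beta_A_grid)
            * len(self.gamma_U_grid)
            * len(self.beta_U_grid)
            * len(self.beta_UA_grid)
            * len(self.gamma_UA_grid)
            * len(self.sigma_Y_grid)
            * len(self.p_missing_grid)
        )

    @property
    def n_deterministic(self) -> int:
        if not self.include_deterministic:
            return 0
        return (
            len(self.alpha_U_grid)
            * len(self.gamma_U_grid)
            * len(self.gamma_UA_grid)
            * len(self.sigma_Y_grid)
            * len(self.det_pi_U_grid)
        )


def enumerate_grid(spec: GridSpec = GridSpec()) -> List[ScenarioConfig]:
    """All scenario configurations of the design, in a stable order.

    Logistic-stratum cells first (ids ``L...``), then the deterministic
    stratum (ids ``D...``); each config carries its stable cell id.
    """
    configs: List[ScenarioConfig] = []
    for i, (a_U, b_A, g_U, b_U, b_UA, g_UA, s_Y, pm) in enumerate(
        itertools.product(
            spec.alpha_U_grid,
            spec.beta_A_grid,
            spec.gamma_U_grid,
            spec.beta_U_grid,
            spec.beta_UA_grid,
            spec.gamma_UA_grid,
            spec.sigma_Y_grid,
            spec.p_missing_grid,
        )
    ):
        configs.append(
            ScenarioConfig(
                pi_U=spec.pi_U,
                alpha_U=a_U,
                sigma_A=spec.sigma_A,
                missingness_kind=LOGISTIC,
                beta_U=b_U,
                beta_A=b_A,
                beta_UA=b_UA,
                target_p_missing=pm,
                gamma_U=g_U,
                gamma_A=spec.gamma_A,
                gamma_UA=g_UA,
                sigma_Y=s_Y,
                n=spec.n,
                cell_id=f"L{i:05d}",
            )
        )
    if spec.include_deterministic:
        for i, (a_U, g_U, g_UA, s_Y, pi_U) in enumerate(
            itertools.product(
                spec.alpha_U_grid,
                spec.gamma_U_grid,
                spec.gamma_UA_grid,
                spec.sigma_Y_grid,
                spec.det_pi_U_grid,
            )
        ):
            configs.append(
                ScenarioConfig(
                    pi_U=pi_U,
                    alpha_U=a_U,
                    sigma_A=spec.sigma_A,
                    missingness_kind=DETERMINISTIC,
                    gamma_U=g_U,
                    gamma_A=spec.gamma_A,
                    gamma_UA=g_UA,
                    sigma_Y=s_Y,
                    n=spec.n,
                    cell_id=f"D{i:04d}",
                )
            )
    expected = spec.n_logistic + spec.n_deterministic
    assert len(configs) == expected, "grid enumeration lost cells"
    return configs


def _replicate_seed(study_seed: int, cell_index: int, replicate: int, stage: int):
    return np.random.SeedSequence([study_seed, cell_index, replicate, stage])


def _record_rows(
    rows: List[dict],
    replicate: int,
    method: str,
    u_observed: bool,
    summary: pd.DataFrame,
    dropped: Tuple[str, ...],
) -> None:
    for coef, r in summary.iterrows():
        rows.append(
            {
                "replicate": replicate,
                "method": method,
                "u_observed": u_observed,
                "coefficient": coef,
                "estimate": r["estimate"],
                "se": r["se"],
                "df": r["df"],
                "ci_lower": r["ci_lower"],
                "ci_upper": r["ci_upper"],
                "failed": False,
                "failure_reason": "",
                "dropped": ";".join(dropped),
            }
        )


def _failure_row(replicate, method, u_observed, reason) -> dict:
    return {
        "replicate": replicate,
        "method": method,
        "u_observed": u_observed,
        "coefficient": "A",
        "estimate": np.nan,
        "se": np.nan,
        "df": np.nan,
        "ci_lower": np.nan,
        "ci_upper": np.nan,
        "failed": True,
        "failure_reason": str(reason),
        "dropped": "",
    }


def run_replicate(
    config: ScenarioConfig,
    replicate: int,
    study_seed: int,
    cell_index: int = 0,
    m: int = 5,
    u_variants: Sequence[bool] = (False, True),
    methods: Sequence[str] = ALL_METHODS,
    alpha: float = 0.05,
) -> List[dict]:
    """Generate one replicate and fit every requested analysis on it.

    Returns tidy per-coefficient records. Fit failures (degenerate
    replicates, too few complete rows) are recorded as failure rows, never
    silently dropped.
    """
    rows: List[dict] = []
    data_seed = _replicate_seed(study_seed, cell_index, replicate, 0)
    ds = generate_dataset(config, data_seed)
    for u_obs in u_variants:
        if "CC" in methods:
            try:
                fit = fit_complete_case(ds, u_observed=u_obs)
                _record_rows(
                    rows, replicate, "CC", u_obs, fit.summary_frame(alpha), fit.dropped
                )
            except FitFailure as exc:
                rows.append(_failure_row(replicate, "CC", u_obs, exc))
        if "Completed" in methods:
            try:
                fit = fit_completed_data(ds, u_observed=u_obs)
                _record_rows(
                    rows,
                    replicate,
                    "Completed",
                    u_obs,
                    fit.summary_frame(alpha),
                    fit.dropped,
                )
            except FitFailure as exc:
                rows.append(_failure_row(replicate, "Completed", u_obs, exc))
        mi_requested = [mm for mm in MI_MODELS if mm in methods]
        if not mi_requested:
            continue
        spec = ImputationModelSpec(u_observed=u_obs, m=m)
        imp_seed = _replicate_seed(study_seed, cell_index, replicate, 1 + int(u_obs))
        try:
            completed = draw_proper_imputations(ds, spec, imp_seed)
        except FitFailure as exc:
            for mm in mi_requested:
                rows.append(_failure_row(replicate, mm, u_obs, exc))
            continue
        for mm in mi_requested:
            try:
                fits = [fit_outcome_model(c, mm, u_observed=u_obs) for c in completed]
                pooled = pool_rubin(fits, alpha=alpha)
                _record_rows(
                    rows,
                    replicate,
                    mm,
                    u_obs,
                    pooled.summary_frame(alpha),
                    fits[0].dropped,
                )
            except (FitFailure, ValueError) as exc:
                rows.append(_failure_row(replicate, mm, u_obs, exc))
    return rows


def coverage(
    estimates: Sequence[float],
    cis: Sequence[Tuple[float, float]],
    target: float = 1.0,
) -> float:
    """Fraction of confidence intervals containing the target value."""
    if len(estimates) != len(cis):
        raise ValueError("estimates and CIs must have equal length")
    if len(cis) == 0:
        raise ValueError("coverage is undefined for empty input")
    hits = [lo <= target <= hi for lo, hi in cis]
    return float(np.mean(hits))


def summarize_estimates(
    estimates: pd.DataFrame,
    targets: Optional[Dict[str, float]] = None,
    percentiles: Sequence[float] = PERCENTILES,
) -> pd.DataFrame:
    """Per (method, confounder-use, coefficient) replicate summaries.

    Retains the estimate percentiles (linear interpolation between order
    statistics), mean and median, the empirical SE (SD of estimates across
    replicates), the mean model-based SE, the mean CI length, the coverage
    of the coefficient's target value, and the failure count. Targets
    default to 1 for the exposure coefficient; coefficients without a
    target get NaN coverage.
    """
    if targets is None:
        targets = {"A": 1.0}
    out = []
    for (method, u_obs, coef), g in estimates.groupby(
        ["method", "u_observed", "coefficient"], sort=True
    ):
        ok = g[~g["failed"]]
        n_failed = int(g["failed"].sum())
        row: Dict[str, object] = {
            "method": method,
            "u_observed": u_obs,
            "coefficient": coef,
            "n_reps": len(g),
            "n_failed": n_failed,
        }
        if len(ok) == 0:
            out.append(row)
            continue
        est = ok["estimate"].to_numpy()
        for p, v in zip(percentiles, np.percentile(est, percentiles)):
            row[f"p{p:g}"] = v
        row["mean"] = est.mean()
        row["median"] = float(np.median(est))
        row["empirical_se"] = est.std(ddof=1) if len(est) > 1 else np.nan
        row["mean_model_se"] = ok["se"].mean()
        row["mean_ci_length"] = (ok["ci_upper"] - ok["ci_lower"]).mean()
        if coef in targets:
            row["target"] = targets[coef]
            row["coverage"] = coverage(
                est, list(zip(ok["ci_lower"], ok["ci_upper"])), targets[coef]
            )
        else:
            row["target"] = np.nan
            row["coverage"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


@dataclass
class CellResult:
    """Per-replicate estimates and their summaries for one grid cell."""

    config: ScenarioConfig
    estimates: pd.DataFrame
    summary: pd.DataFrame

    @property
    def n_failures(self) -> int:
        return int(self.estimates["failed"].sum())


def run_cell(
    config: ScenarioConfig,
    replicates: int,
    study_seed: int,
    cell_index: int = 0,
    m: int = 5,
    u_variants: Sequence[bool] = (False, True),
    methods: Sequence[str] = ALL_METHODS,
    targets: Optional[Dict[str, float]] = None,
    alpha: float = 0.05,
) -> CellResult:
    """Run all replicates of one cell and summarize.

    Summaries are over successful replicates; failures are counted in an
    explicit column of the summary, never dropped silently.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rows: List[dict] = []
    for r in range(replicates):
        rows.extend(
            run_replicate(
                config,
                r,
                study_seed,
                cell_index=cell_index,
                m=m,
                u_variants=u_variants,
                methods=methods,
                alpha=alpha,
            )
        )
    estimates = pd.DataFrame(rows)
    summary = summarize_estimates(estimates, targets=targets)
    summary.insert(0, "cell_id", config.cell_id or "")
    summary.insert(1, "scenario", config.scenario_label)
    return CellResult(config=config, estimates=estimates, summary=summary)


def run_grid(
    configs: Sequence[ScenarioConfig],
    replicates: int,
    study_seed: int,
    m: int = 5,
    n_jobs: int = 1,
    u_variants: Sequence[bool] = (False, True),
    methods: Sequence[str] = ALL_METHODS,
    targets: Optional[Dict[str, float]] = None,
    cell_indices: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Run many cells (optionally in parallel) and stack their summaries.

    ``cell_indices`` pins each config's seeding index so that a filtered
    subset reproduces the corresponding cells of the full grid; by default
    configs are indexed by position.
    """
    if cell_indices is None:
        cell_indices = list(range(len(configs)))

    def one(cfg: ScenarioConfig, idx: int) -> pd.DataFrame:
        return run_cell(
            cfg,
            replicates,
            study_seed,
            cell_index=idx,
            m=m,
            u_variants=u_variants,
            methods=methods,
            targets=targets,
        ).summary

    if n_jobs == 1:
        parts = [one(c, i) for c, i in zip(configs, cell_indices)]
    else:
        parts = Parallel(n_jobs=n_jobs)(
            delayed(one)(c, i) for c, i in zip(configs, cell_indices)
        )
    return pd.concat(parts, ignore_index=True)


def tidy_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide summary into one row per (cell, method, coefficient, statistic)."""
    id_cols = [
        c
        for c in ("cell_id", "scenario", "method", "u_observed", "coefficient")
        if c in summary.columns
    ]
    value_cols = [c for c in summary.columns if c not in id_cols]
    return summary.melt(
        id_vars=id_cols, value_vars=value_cols, var_name="statistic", value_name="value"
    )
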