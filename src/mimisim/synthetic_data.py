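"""Hand-checkable fixtures and the per-figure scenario presets.

Two kinds of fixtures live here: tiny synthetic datasets whose analysis
results can be verified by hand (a noiseless linear toy, a six-row dataset
for checking fits against the normal equations), and the panel presets —
checked-in YAML files, one per results figure, from which a fully solved
:class:`~mimisim.dgm.ScenarioConfig` for any displayed panel cell can be
built. Tests and documentation share these files with the command-line
interface.
"""

from __future__ import annotations

import importlib.resources
from typing import Dict, List, Union

import numpy as np
import pandas as pd
import yaml

from .dgm import DETERMINISTIC, ScenarioConfig, SimDataset, as_rng
from .imputation import CompletedDataset

__all__ = [
    "figure_preset",
    "load_figure_spec",
    "available_figures",
    "noiseless_toy",
    "hand_ols_dataset",
    "CATALOGUE",
]

DETERMINISTIC_ROW = "deterministic"


def _preset_text(figure: int) -> str:
    res = importlib.resources.files("mimisim").joinpath(f"presets/fig{figure}.yaml")
    return res.read_text()


def available_figures() -> List[int]:
    return [2, 3, 4, 5, 6, 7]


def load_figure_spec(figure: int) -> dict:
    """Raw panel-grid description of one results figure."""
    if figure not in available_figures():
        raise ValueError(f"no preset for figure {figure}")
    return yaml.safe_load(_preset_text(figure))


def figure_preset(
    figure: int, row: Union[float, str], axis: float
) -> ScenarioConfig:
    """A solved scenario configuration for one panel cell of a figure.

    ``row`` selects the between-panel parameter (the confounder-missingness
    slope; the string ``"deterministic"`` selects the extreme
    ``R_A = 1 - U`` row where a figure shows it) and ``axis`` the parameter
    varied within a panel. Selectors outside the displayed grid raise.
    The resulting configuration is validated against the scenario labels
    the figure covers.
    """
    spec = load_figure_spec(figure)
    row_vals = spec["rows"]["values"]
    axis_vals = spec["axis"]["values"]
    if row not in row_vals:
        raise ValueError(f"row {row!r} not in figure {figure} grid {row_vals}")
    if axis not in axis_vals:
        raise ValueError(f"axis {axis!r} not in figure {figure} grid {axis_vals}")
    params: Dict[str, object] = dict(spec["fixed"])
    params["u_observed"] = spec["u_observed"]
    params[spec["axis"]["parameter"]] = axis
    if row == DETERMINISTIC_ROW:
        params["missingness_kind"] = DETERMINISTIC
        for redundant in ("beta_U", "beta_A", "beta_UA", "target_p_missing"):
            params.pop(redundant, None)
    else:
        params[spec["rows"]["parameter"]] = row
    params["cell_id"] = f"fig{figure}[{row},{axis}]"
    config = ScenarioConfig(**params)
    if config.scenario_label not in spec["scenarios"]:
        raise ValueError(
            f"figure {figure} preset produced scenario {config.scenario_label!r}, "
            f"outside its declared set {spec['scenarios']}"
        )
    return config


def noiseless_toy(
    n: int = 40, slope: float = 3.0, missing_frac: float = 0.5, seed: int = 0
) -> SimDataset:
    """Synthetic noiseless toy: the outcome is exactly ``slope * A``.

    Half the exposure values (a random subset) are masked completely at
    random; any correct complete-case fit recovers the slope with zero
    residual. The attached configuration is nominal metadata only — the
    columns are constructed directly, not drawn from the structural models.
    """
    rng = as_rng(seed)
    A = rng.normal(0.0, 1.0, size=n)
    Y = slope * A
    R_A = np.ones(n, dtype=int)
    R_A[rng.permutation(n)[: int(round(missing_frac * n))]] = 0
    frame = pd.DataFrame(
        {
            "U": np.zeros(n, dtype=int),
            "A": A,
            "R_A": R_A,
            "A_star": np.where(R_A == 1, A, np.nan),
            "Y": Y,
        }
    )
    config = ScenarioConfig(
        gamma_A=slope, target_p_missing=missing_frac, n=n, cell_id="toy-noiseless"
    )
    return SimDataset(frame=frame, config=config, seed=seed)


def hand_ols_dataset() -> CompletedDataset:
    """Six-row completed dataset with fixed numbers for hand verification.

    The imputed-exposure column, missingness indicator and outcome are
    small integers/halves so that any outcome-model fit can be checked
    against a normal-equations solve done by hand (or an independent
    solver).
    """
    frame = pd.DataFrame(
        {
            "U": [0, 1, 0, 1, 0, 1],
            "A": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "R_A": [1, 1, 1, 0, 0, 1],
            "A_star": [1.0, 2.0, 3.0, np.nan, np.nan, 6.0],
            "Y": [1.5, 2.0, 3.5, 3.0, 5.5, 6.0],
            "A_imp": [1.0, 2.0, 3.0, 4.5, 4.0, 6.0],
        }
    )
    config = ScenarioConfig(target_p_missing=1.0 / 3.0, n=6, cell_id="toy-hand-ols")
    return CompletedDataset(frame=frame, config=config, imputation_index=0)


CATALOGUE = {
    "noiseless_toy": noiseless_toy,
    "hand_ols_dataset": hand_ols_dataset,
    "figure_preset": figure_preset,
}
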