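import numpy as np
import pytest

from mimisim.dgm import DETERMINISTIC, ScenarioConfig


@pytest.fixture
def scenario_i_config() -> ScenarioConfig:
    """MCAR cell: no edges into the missingness indicator, no confounding."""
    return ScenarioConfig(
        pi_U=0.5,
        alpha_U=0.0,
        beta_U=0.0,
        beta_A=0.0,
        beta_UA=0.0,
        target_p_missing=0.5,
        gamma_U=1.0,
        gamma_A=1.0,
        gamma_UA=0.0,
        sigma_Y=1.0,
        n=10_000,
    )


@pytest.fixture
def deterministic_config() -> ScenarioConfig:
    """Extreme confounder-driven missingness: R_A = 1 - U."""
    return ScenarioConfig(
        pi_U=0.5,
        alpha_U=0.0,
        missingness_kind=DETERMINISTIC,
        gamma_U=1.0,
        gamma_A=1.0,
        gamma_UA=0.0,
        sigma_Y=1.0,
        n=10_000,
    )


def mc_se(values: np.ndarray) -> float:
    """Monte-Carlo standard error of the mean of replicate estimates."""
    values = np.asarray(values)
    return values.std(ddof=1) / np.sqrt(len(values))
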