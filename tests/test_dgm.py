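"""Structural-model generator: intercept solving, masking, DAG faithfulness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from scipy.special import expit

from mimisim.dgm import (
    DETERMINISTIC,
    ScenarioConfig,
    classify_scenario,
    generate_dataset,
    marginal_p_missing,
    solve_alpha0,
    solve_beta0,
    solve_gamma0,
)


@pytest.mark.parametrize(
    "alpha_U, pi_U, expected",
    [(0.0, 0.5, 0.0), (1.0, 0.5, -0.5), (0.5, 0.25, -0.125)],
)
def test_solve_alpha0(alpha_U, pi_U, expected):
    assert solve_alpha0(alpha_U, pi_U) == pytest.approx(expected)


def test_solve_alpha0_centres_exposure():
    """Monte Carlo: with the solved intercept the exposure mean is zero."""
    cfg = ScenarioConfig(alpha_U=1.0, pi_U=0.5, target_p_missing=0.5, n=1_000_000)
    a = generate_dataset(cfg, 123).frame["A"]
    assert abs(a.mean()) < 3 * a.std() / np.sqrt(len(a))


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(gamma_U=0, gamma_A=0, gamma_UA=0, pi_U=0.5, alpha_0=0, alpha_U=0), 0.0),
        (dict(gamma_U=1, gamma_A=1, gamma_UA=0, pi_U=0.5, alpha_0=0, alpha_U=0), -0.5),
        (
            dict(gamma_U=1, gamma_A=1, gamma_UA=0.5, pi_U=0.5, alpha_0=-0.5, alpha_U=1),
            -0.625,
        ),
    ],
)
def test_solve_gamma0(kwargs, expected):
    assert solve_gamma0(**kwargs) == pytest.approx(expected)


def test_solve_gamma0_centres_outcome():
    cfg = ScenarioConfig(
        alpha_U=1.0, gamma_U=1.0, gamma_UA=0.5, target_p_missing=0.5, n=1_000_000
    )
    y = generate_dataset(cfg, 321).frame["Y"]
    assert abs(y.mean()) < 3 * y.std() / np.sqrt(len(y))


def test_solve_beta0_closed_forms():
    assert solve_beta0(0.5, 0, 0, 0, 0.5, 0, 0, 1) == pytest.approx(0.0, abs=1e-9)
    assert solve_beta0(0.25, 0, 0, 0, 0.5, 0, 0, 1) == pytest.approx(
        np.log(0.25 / 0.75), abs=1e-9
    )


def test_solve_beta0_achieves_target_in_simulation():
    """The achieved missingness fraction matches the target at large n."""
    cfg = ScenarioConfig(
        beta_U=1.0, beta_A=0.5, beta_UA=0.0, target_p_missing=0.5, n=1_000_000
    )
    ds = generate_dataset(cfg, 7)
    assert ds.n_missing / ds.n == pytest.approx(0.5, abs=0.002)


def test_marginal_p_missing_against_adaptive_quadrature():
    """The Gauss-Hermite expectation agrees with an independent integrator."""
    params = dict(
        beta_0=-0.3, beta_U=0.8, beta_A=0.6, beta_UA=0.5,
        pi_U=0.3, alpha_0=-0.15, alpha_U=0.5, sigma_A=1.2,
    )

    def stratum(u):
        mu = params["alpha_0"] + params["alpha_U"] * u
        off = params["beta_0"] + params["beta_U"] * u
        slope = params["beta_A"] + params["beta_UA"] * u
        f = lambda a: expit(off + slope * a) * stats.norm.pdf(
            a, mu, params["sigma_A"]
        )
        val, _ = integrate.quad(f, mu - 12 * params["sigma_A"], mu + 12 * params["sigma_A"])
        return val

    expected = (1 - params["pi_U"]) * stratum(0) + params["pi_U"] * stratum(1)
    assert marginal_p_missing(**params) == pytest.approx(expected, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    target=st.floats(0.05, 0.95),
    beta_U=st.floats(-2, 2),
    beta_A=st.floats(-2, 2),
    beta_UA=st.floats(-1, 1),
    alpha_U=st.floats(-1, 1),
    pi_U=st.floats(0.1, 0.9),
)
def test_solve_beta0_hits_target(target, beta_U, beta_A, beta_UA, alpha_U, pi_U):
    """Property: the solved intercept reproduces the requested proportion."""
    alpha_0 = solve_alpha0(alpha_U, pi_U)
    b0 = solve_beta0(target, beta_U, beta_A, beta_UA, pi_U, alpha_0, alpha_U, 1.0)
    achieved = marginal_p_missing(b0, beta_U, beta_A, beta_UA, pi_U, alpha_0, alpha_U, 1.0)
    assert achieved == pytest.approx(target, abs=1e-6)


def test_generated_missing_fraction_within_binomial_bound(scenario_i_config):
    ds = generate_dataset(scenario_i_config, 99)
    assert ds.n_missing / ds.n == pytest.approx(0.5, abs=0.015)


def test_deterministic_missingness_is_exactly_one_minus_u(deterministic_config):
    ds = generate_dataset(deterministic_config, 5)
    f = ds.frame
    assert ((f["R_A"] + f["U"]) == 1).all()
    assert ds.n_missing == int(f["U"].sum())


def test_mcar_null_correlations(scenario_i_config):
    """Scenario (i): the missingness indicator is uncorrelated with U, A, Y.

    Null band 3.5 / sqrt(n) for a sample correlation under independence.
    """
    cfg = ScenarioConfig(**{**scenario_i_config.to_dict(), "n": 50_000})
    f = generate_dataset(cfg, 11).frame
    for col in ["U", "A", "Y"]:
        assert abs(np.corrcoef(f["R_A"], f[col])[0, 1]) < 3.5 / np.sqrt(cfg.n)


def _partial_corr(x, y, z):
    rx = x - np.polyval(np.polyfit(z, x, 1), z)
    ry = y - np.polyval(np.polyfit(z, y, 1), z)
    return np.corrcoef(rx, ry)[0, 1]


def test_dag_faithfulness_partial_correlations():
    """Scenario (iv): R_A independent of U given A; (ii): of A given U."""
    cfg_iv = ScenarioConfig(beta_A=1.0, beta_U=0.0, beta_UA=0.0, target_p_missing=0.5,
                            alpha_U=0.0, gamma_U=1.0, n=10_000)
    f = generate_dataset(cfg_iv, 2).frame
    assert abs(_partial_corr(f["R_A"], f["U"], f["A"])) < 0.03

    cfg_ii = ScenarioConfig(beta_U=1.0, beta_A=0.0, beta_UA=0.0, target_p_missing=0.5,
                            alpha_U=0.0, gamma_U=1.0, n=10_000)
    f = generate_dataset(cfg_ii, 3).frame
    assert abs(_partial_corr(f["R_A"], f["A"], f["U"])) < 0.03


def test_same_seed_is_bit_identical(scenario_i_config):
    f1 = generate_dataset(scenario_i_config, 42).frame
    f2 = generate_dataset(scenario_i_config, 42).frame
    assert f1.equals(f2)


def test_a_star_masks_exactly_where_missing(scenario_i_config):
    f = generate_dataset(scenario_i_config, 8).frame
    obs = f["R_A"] == 1
    assert (f.loc[obs, "A_star"] == f.loc[obs, "A"]).all()
    assert f.loc[~obs, "A_star"].isna().all()


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(pi_U=0.0, target_p_missing=0.5),
        dict(pi_U=1.2, target_p_missing=0.5),
        dict(sigma_A=0.0, target_p_missing=0.5),
        dict(sigma_Y=-1.0, target_p_missing=0.5),
        dict(n=1, target_p_missing=0.5),
        dict(missingness_kind="bogus", target_p_missing=0.5),
        dict(missingness_kind=DETERMINISTIC, beta_U=1.0),
        dict(missingness_kind=DETERMINISTIC, target_p_missing=0.5),
        dict(),  # logistic without a missingness target
    ],
)
def test_config_validation_rejects(kwargs):
    with pytest.raises(ValueError):
        ScenarioConfig(**kwargs)


@pytest.mark.parametrize(
    "alpha_U, beta_U, beta_A, beta_UA, det, label",
    [
        (0, 0, 0, 0, False, "i"),
        (0, 1, 0, 0, False, "ii"),
        (1, 1, 0, 0, False, "iii"),
        (0, 0, 1, 0, False, "iv"),
        (0, 1, 1, 0, False, "v"),
        (0, 0, 0, 0.5, False, "v"),  # the interaction opens both edges
        (1, 1, 1, 0, False, "vi"),
        (0, None, None, None, True, "ii"),
        (0.5, None, None, None, True, "iii"),
    ],
)
def test_scenario_classification(alpha_U, beta_U, beta_A, beta_UA, det, label):
    assert classify_scenario(alpha_U, beta_U, beta_A, beta_UA, det) == label


def test_require_scenario_and_u_suffix(deterministic_config):
    assert deterministic_config.require_scenario("ii") is deterministic_config
    with pytest.raises(ValueError):
        deterministic_config.require_scenario("iv")
    cfg = ScenarioConfig(target_p_missing=0.5, u_observed=True)
    assert cfg.scenario_label == "i-U"


def test_dataset_csv_roundtrip(tmp_path, scenario_i_config):
    """Delimited output preserves values; missing entries are empty fields."""
    import pandas as pd

    cfg = ScenarioConfig(**{**scenario_i_config.to_dict(), "n": 50})
    ds = generate_dataset(cfg, 4)
    path = tmp_path / "data.csv"
    ds.to_csv(path)
    text = path.read_text().splitlines()
    assert text[0] == "U,A,R_A,A_star,Y"
    back = pd.read_csv(path)
    assert np.allclose(back["A"], ds.frame["A"])
    assert back["A_star"].isna().equals(ds.frame["A_star"].isna())
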