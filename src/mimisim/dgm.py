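"""Data-generating mechanisms for the missingness / confounding scenarios.

The structural system has four variables, drawn in causal order:

* ``U``  — binary, ``P[U = 1] = pi_U``; possibly unmeasured.
* ``A``  — continuous exposure, ``A ~ N(alpha_0 + alpha_U * U, sigma_A**2)``.
* ``R_A`` — missingness indicator for ``A`` (``R_A = 0`` means missing),
  either logistic, ``P[R_A = 0] = expit(beta_0 + beta_U*U + beta_A*A +
  beta_UA*U*A)``, or deterministic, ``R_A = 1 - U``.
* ``Y``  — continuous outcome,
  ``Y ~ N(gamma_0 + gamma_U*U + gamma_A*A + gamma_UA*U*A, sigma_Y**2)``.

Intercepts are not free parameters: ``alpha_0`` is solved so that
``E[A] = 0``, ``gamma_0`` so that ``E[Y] = 0``, and (for the logistic
mechanism) ``beta_0`` so that the marginal missingness probability
``P[R_A = 0]`` hits a requested target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ScenarioConfig",
    "SimDataset",
    "solve_alpha0",
    "solve_gamma0",
    "solve_beta0",
    "generate_dataset",
    "classify_scenario",
]

LOGISTIC = "logistic"
DETERMINISTIC = "deterministic_1_minus_U"

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

# Gauss-Hermite rule used for Gaussian expectations of expit terms.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)
_BETA0_BRACKET = (-40.0, 40.0)


def solve_alpha0(alpha_U: float, pi_U: float) -> float:
    """Intercept of the exposure model making ``E[A] = 0``.

    ``E[A] = alpha_0 + alpha_U * pi_U``, hence ``alpha_0 = -alpha_U * pi_U``.
    """
    if not 0.0 < pi_U < 1.0:
        raise ValueError(f"pi_U must be in (0, 1), got {pi_U}")
    return -alpha_U * pi_U


def solve_gamma0(
    gamma_U: float,
    gamma_A: float,
    gamma_UA: float,
    pi_U: float,
    alpha_0: float,
    alpha_U: float,
) -> float:
    """Intercept of the outcome model making ``E[Y] = 0``.

    With ``E[A] = 0`` already enforced,
    ``E[Y] = gamma_0 + gamma_U*pi_U + gamma_A*E[A] + gamma_UA*E[U*A]`` and
    ``E[U*A] = pi_U * (alpha_0 + alpha_U)`` (the mean of ``A`` in the
    ``U = 1`` stratum, weighted by its probability).
    """
    e_A = alpha_0 + alpha_U * pi_U
    e_UA = pi_U * (alpha_0 + alpha_U)
    return -(gamma_U * pi_U + gamma_A * e_A + gamma_UA * e_UA)


def _expit_gauss_mean(offset: float, slope: float, mu: float, sigma: float) -> float:
    """``E[expit(offset + slope * A)]`` for ``A ~ N(mu, sigma**2)``.

    Gauss-Hermite quadrature with the substitution ``A = mu + sqrt(2)*sigma*x``.
    """
    a = mu + np.sqrt(2.0) * sigma * _GH_NODES
    return float(_GH_WEIGHTS @ expit(offset + slope * a)) / np.sqrt(np.pi)


def marginal_p_missing(
    beta_0: float,
    beta_U: float,
    beta_A: float,
    beta_UA: float,
    pi_U: float,
    alpha_0: float,
    alpha_U: float,
    sigma_A: float,
) -> float:
    """Marginal ``P[R_A = 0]`` under the logistic missingness model.

    A two-component mixture over the ``U`` strata, each a one-dimensional
    Gaussian integral of an expit.
    """
    p0 = _expit_gauss_mean(beta_0, beta_A, alpha_0, sigma_A)
    p1 = _expit_gauss_mean(
        beta_0 + beta_U, beta_A + beta_UA, alpha_0 + alpha_U, sigma_A
    )
    return (1.0 - pi_U) * p0 + pi_U * p1


@lru_cache(maxsize=4096)
def _solve_beta0_cached(
    target_p_missing: float,
    beta_U: float,
    beta_A: float,
    beta_UA: float,
    pi_U: float,
    alpha_0: float,
    alpha_U: float,
    sigma_A: float,
) -> float:
    # Collapse the two U-strata quadratures into one weighted node vector:
    # P[R_A = 0](b0) = sum_i w_i expit(b0 + c_i), strictly increasing in b0.
    shift = np.sqrt(2.0) * sigma_A * _GH_NODES
    c = np.concatenate(
        [
            beta_A * (alpha_0 + shift),
            beta_U + (beta_A + beta_UA) * (alpha_0 + alpha_U + shift),
        ]
    )
    w = np.concatenate(
        [(1.0 - pi_U) * _GH_WEIGHTS, pi_U * _GH_WEIGHTS]
    ) / np.sqrt(np.pi)

    lo, hi = _BETA0_BRACKET
    p_lo = float(w @ expit(lo + c))
    p_hi = float(w @ expit(hi + c))
    if not (p_lo < target_p_missing < p_hi):
        raise RuntimeError(
            "beta_0 root not bracketed on "
            f"[{lo}, {hi}]: P({lo})={p_lo:.3g}, P({hi})={p_hi:.3g}"
        )
    # Newton iteration safeguarded by bisection on the maintained bracket.
    b0 = float(np.log(target_p_missing / (1.0 - target_p_missing)))
    for _ in range(100):
        e = expit(b0 + c)
        diff = float(w @ e) - target_p_missing
        if abs(diff) < 1e-12:
            break
        if diff > 0:
            hi = b0
        else:
            lo = b0
        deriv = float(w @ (e * (1.0 - e)))
        nxt = b0 - diff / deriv if deriv > 0 else 0.5 * (lo + hi)
        b0 = nxt if lo < nxt < hi else 0.5 * (lo + hi)
    return b0


def solve_beta0(
    target_p_missing: float,
    beta_U: float,
    beta_A: float,
    beta_UA: float,
    pi_U: float,
    alpha_0: float,
    alpha_U: float,
    sigma_A: float,
) -> float:
    """Logistic intercept achieving a marginal missingness proportion.

    Solves ``P[R_A = 0] = target_p_missing``, where the marginal probability
    mixes one-dimensional Gaussian integrals of the expit over the two ``U``
    strata (see :func:`marginal_p_missing`), evaluated by Gauss-Hermite
    quadrature. The probability is strictly increasing in ``beta_0``, so a
    bracketed Newton iteration converges to the unique root; results are
    cached because factorial grids revisit the same slope combinations.
    """
    if not 0.0 < target_p_missing < 1.0:
        raise ValueError("target_p_missing must be in (0, 1)")
    return _solve_beta0_cached(
        float(target_p_missing),
        float(beta_U),
        float(beta_A),
        float(beta_UA),
        float(pi_U),
        float(alpha_0),
        float(alpha_U),
        float(sigma_A),
    )


def classify_scenario(
    alpha_U: float,
    beta_U: Optional[float],
    beta_A: Optional[float],
    beta_UA: Optional[float],
    deterministic: bool,
) -> str:
    """Map a parameter zero-pattern to its causal-diagram scenario label.

    The six scenarios are distinguished by which edges enter ``R_A`` and
    whether ``U`` confounds the exposure-outcome relation (``alpha_U != 0``):

    * (i)   no edges into ``R_A``, no confounding (MCAR);
    * (ii)  ``U -> R_A`` only, no confounding;
    * (iii) ``U -> R_A`` with confounding;
    * (iv)  ``A -> R_A`` only, no confounding;
    * (v)   ``U -> R_A`` and ``A -> R_A``, no confounding;
    * (vi)  any remaining pattern (the unconstrained case).

    The deterministic mechanism ``R_A = 1 - U`` is the extreme of the
    ``U -> R_A`` edge, hence scenario (ii) or (iii).
    """
    if deterministic:
        u_edge, a_edge = True, False
    else:
        u_edge = bool(beta_U) or bool(beta_UA)
        a_edge = bool(beta_A) or bool(beta_UA)
    confounded = bool(alpha_U)
    if not u_edge and not a_edge:
        base = "i"
    elif u_edge and not a_edge:
        base = "ii"
    elif a_edge and not u_edge:
        base = "iv"
    else:
        base = "v"
    if confounded:
        base = "iii" if base == "ii" else "vi"
    return base


@dataclass(frozen=True)
class ScenarioConfig:
    """All structural parameters for one simulation cell.

    Only the free parameters are supplied; the three intercepts are solved
    in ``__post_init__`` to satisfy the moment constraints ``E[A] = 0``,
    ``E[Y] = 0`` and (logistic mechanism) ``P[R_A = 0] = target_p_missing``.

    Parameters
    ----------
    pi_U : probability of ``U = 1``.
    alpha_U : effect of ``U`` on the exposure mean.
    sigma_A : residual SD of the exposure.
    missingness_kind : ``"logistic"`` or ``"deterministic_1_minus_U"``.
    beta_U, beta_A, beta_UA : logistic slopes; must be ``None`` for the
        deterministic mechanism, where they are redundant.
    target_p_missing : marginal ``P[R_A = 0]`` the solved intercept must
        achieve; ``None`` for the deterministic mechanism (there the
        missingness proportion is ``pi_U`` by construction).
    gamma_U, gamma_A, gamma_UA : outcome-model effects.
    sigma_Y : residual SD of the outcome.
    u_observed : whether analyses may use ``U`` (scenario suffix ``-U``).
    n : observations per simulated replicate.
    """

    pi_U: float = 0.5
    alpha_U: float = 0.0
    sigma_A: float = 1.0
    missingness_kind: str = LOGISTIC
    beta_U: Optional[float] = None
    beta_A: Optional[float] = None
    beta_UA: Optional[float] = None
    target_p_missing: Optional[float] = None
    gamma_U: float = 0.0
    gamma_A: float = 1.0
    gamma_UA: float = 0.0
    sigma_Y: float = 1.0
    u_observed: bool = False
    n: int = 10_000
    cell_id: Optional[str] = None
    # derived intercepts -- solved, never user-set
    alpha_0: float = field(init=False)
    beta_0: Optional[float] = field(init=False)
    gamma_0: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_U < 1.0:
            raise ValueError(f"pi_U must be in (0, 1), got {self.pi_U}")
        if self.sigma_A <= 0 or self.sigma_Y <= 0:
            raise ValueError("sigma_A and sigma_Y must be positive")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.missingness_kind == DETERMINISTIC:
            for name in ("beta_U", "beta_A", "beta_UA", "target_p_missing"):
                if getattr(self, name) is not None:
                    raise ValueError(
                        f"{name} is redundant under R_A = 1 - U and must be None"
                    )
        elif self.missingness_kind == LOGISTIC:
            if self.target_p_missing is None:
                raise ValueError("logistic missingness requires target_p_missing")
            for name in ("beta_U", "beta_A", "beta_UA"):
                if getattr(self, name) is None:
                    object.__setattr__(self, name, 0.0)
        else:
            raise ValueError(f"unknown missingness_kind {self.missingness_kind!r}")

        a0 = solve_alpha0(self.alpha_U, self.pi_U)
        object.__setattr__(self, "alpha_0", a0)
        if self.missingness_kind == LOGISTIC:
            b0 = solve_beta0(
                self.target_p_missing,
                self.beta_U,
                self.beta_A,
                self.beta_UA,
                self.pi_U,
                a0,
                self.alpha_U,
                self.sigma_A,
            )
        else:
            b0 = None
        object.__setattr__(self, "beta_0", b0)
        object.__setattr__(
            self,
            "gamma_0",
            solve_gamma0(
                self.gamma_U, self.gamma_A, self.gamma_UA, self.pi_U, a0, self.alpha_U
            ),
        )

    @property
    def deterministic(self) -> bool:
        return self.missingness_kind == DETERMINISTIC

    @property
    def scenario_label(self) -> str:
        base = classify_scenario(
            self.alpha_U, self.beta_U, self.beta_A, self.beta_UA, self.deterministic
        )
        return f"{base}-U" if self.u_observed else base

    @property
    def p_missing(self) -> float:
        """Marginal ``P[R_A = 0]`` implied by the configuration."""
        if self.deterministic:
            return self.pi_U
        return self.target_p_missing

    def require_scenario(self, label: str) -> "ScenarioConfig":
        """Assert that the parameter zero-pattern matches a declared label."""
        if self.scenario_label != label:
            raise ValueError(
                f"parameters imply scenario {self.scenario_label!r}, "
                f"not the declared {label!r}"
            )
        return self

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("alpha_0", "beta_0", "gamma_0"):
            d.pop(k)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for k in ("alpha_0", "beta_0", "gamma_0", "scenario_label"):
            d.pop(k, None)
        return cls(**d)


def as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimDataset:
    """One simulated replicate.

    ``frame`` holds columns ``U``, ``A`` (complete, for benchmarking),
    ``R_A`` (0 = missing), ``A_star`` (``A`` where observed, NaN where
    missing) and ``Y``. ``degenerate`` flags replicates in which every
    value of ``A`` is observed or every value is missing; such replicates
    are returned as-is and the caller decides how to account for them.
    """

    frame: pd.DataFrame
    config: ScenarioConfig
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_observed(self) -> int:
        return int(self.frame["R_A"].sum())

    @property
    def n_missing(self) -> int:
        return self.n - self.n_observed

    @property
    def degenerate(self) -> bool:
        return self.n_observed in (0, self.n)

    @property
    def missing_indicator(self) -> np.ndarray:
        """The indicator ``1 - R_A`` entered as a covariate in MIMI models."""
        return 1 - self.frame["R_A"].to_numpy()

    def to_csv(self, path) -> None:
        """Write the dataset as delimited text (missing ``A_star`` empty)."""
        self.frame.to_csv(path, index=False)


def generate_dataset(config: ScenarioConfig, seed: SeedLike) -> SimDataset:
    """Draw one replicate under the structural models, in causal order.

    ``U -> A -> R_A -> Y``; the observable exposure ``A_star`` equals ``A``
    where ``R_A = 1`` and is NaN where ``R_A = 0``. Repeated calls with the
    same ``(config, seed)`` are bit-identical.
    """
    rng = as_rng(seed)
    n = config.n
    U = rng.binomial(1, config.pi_U, size=n)
    A = rng.normal(config.alpha_0 + config.alpha_U * U, config.sigma_A, size=n)
    if config.deterministic:
        R_A = 1 - U
    else:
        p_miss = expit(
            config.beta_0
            + config.beta_U * U
            + config.beta_A * A
            + config.beta_UA * U * A
        )
        R_A = 1 - rng.binomial(1, p_miss)
    Y = rng.normal(
        config.gamma_0
        + config.gamma_U * U
        + config.gamma_A * A
        + config.gamma_UA * U * A,
        config.sigma_Y,
        size=n,
    )
    A_star = np.where(R_A == 1, A, np.nan)
    frame = pd.DataFrame(
        {"U": U, "A": A, "R_A": R_A, "A_star": A_star, "Y": Y}
    )
    stored_seed = seed if isinstance(seed, int) else None
    return SimDataset(frame=frame, config=config, seed=stored_seed)
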