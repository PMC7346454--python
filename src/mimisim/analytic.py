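"""Closed-form oracles: true causal effects and the regression-dilution bias.

These quantities anchor the simulation summaries: the standardized
(unconditional) causal effect sets the coverage target per cell, and the
dilution formula predicts the expectation of the missing-indicator
coefficient in the deterministic-missingness special case.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CausalTargets", "true_effects", "dilution_attenuation"]


@dataclass(frozen=True)
class CausalTargets:
    """True causal effects of a one-unit increase in the exposure.

    ``delta_A`` is the unconditional effect obtained by standardization over
    the confounder distribution; the conditional effects given ``U = 0`` and
    ``U = 1`` are ``gamma_A`` and ``gamma_A + gamma_UA``.
    """

    delta_A: float
    effect_given_U0: float
    effect_given_U1: float


def true_effects(gamma_A: float, gamma_UA: float, pi_U: float) -> CausalTargets:
    """Standardized and conditional causal effects.

    ``delta_A = gamma_A + pi_U * gamma_UA``: the outcome model is linear in
    the exposure, so the unit effect depends only on ``U``, and averaging the
    two conditional effects over ``P[U = 1] = pi_U`` gives the marginal one.
    """
    if not 0.0 <= pi_U <= 1.0:
        raise ValueError(f"pi_U must be in [0, 1], got {pi_U}")
    return CausalTargets(
        delta_A=gamma_A + pi_U * gamma_UA,
        effect_given_U0=gamma_A,
        effect_given_U1=gamma_A + gamma_UA,
    )


def dilution_attenuation(
    gamma_U: float, gamma_A: float, sigma_A: float, sigma_Y: float
) -> float:
    """Approximate expectation of the missing-indicator coefficient under
    ``R_A = 1 - U`` with no exposure-confounder interaction.

    When every ``U = 1`` row has the exposure missing and imputation draws
    it from its regression on ``Y``, the imputed exposure is a noisy proxy;
    the indicator coefficient in the outcome model then estimates the
    confounder effect attenuated by regression dilution:

        gamma_U * sigma_Y**2 / (gamma_A**2 * sigma_A**2 + sigma_Y**2)

    The exposure coefficient itself remains unbiased for ``gamma_A`` in this
    setting.
    """
    if sigma_A <= 0 or sigma_Y <= 0:
        raise ValueError("sigma_A and sigma_Y must be positive")
    return gamma_U * sigma_Y**2 / (gamma_A**2 * sigma_A**2 + sigma_Y**2)
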