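"""Closed-form representational-similarity (RS) expressions.

These are the analytic expectations for the Pearson correlation between
population-response vectors of two stimulus repeats under the different
stimulus/behaviour mixing models, in the large-population limit.  They
serve as oracles for the Monte-Carlo simulators in
:mod:`driftlab.models`.

All formulas take *standard deviations* of the zero-mean signal, noise
and behavioural-tuning components.  Pearson correlation removes means,
so uniform draws on ``[0, 1]`` enter with SD ``sqrt(1/12)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rs_unscaled",
    "rs_noise_scaled",
    "rs_signal_scaled",
    "rs_both_scaled",
    "rs_independent",
    "rs_independent_frozen_tuning",
    "rs_baseline_dominated",
]


class DegenerateInputError(ValueError):
    """Raised when a closed form is evaluated at an undefined point."""


def rs_unscaled(sigma_s: float, sigma_n: float) -> float:
    """RS of the unscaled additive model ``u = S + N``.

    Signal S is frozen across repeats, noise N redrawn each repeat:
    ``rho = sigma_s^2 / (sigma_s^2 + sigma_n^2)``.
    """
    denom = sigma_s**2 + sigma_n**2
    if denom <= 0:
        raise DegenerateInputError("rs_unscaled undefined for sigma_s = sigma_n = 0")
    return sigma_s**2 / denom


def rs_noise_scaled(sigma_s: float, sigma_n: float, g_i: float, g_j: float) -> float:
    """RS when only the noise is gain-scaled (``u = S + gN``).

    ``rho = sigma_s^2 / sqrt((sigma_s^2 + g_i^2 sigma_n^2)(sigma_s^2 + g_j^2 sigma_n^2))``.
    Larger gains shrink the similarity.
    """
    d_i = sigma_s**2 + g_i**2 * sigma_n**2
    d_j = sigma_s**2 + g_j**2 * sigma_n**2
    if d_i <= 0 or d_j <= 0:
        raise DegenerateInputError("rs_noise_scaled undefined: zero variance")
    return sigma_s**2 / np.sqrt(d_i * d_j)


def rs_signal_scaled(sigma_s: float, sigma_n: float, g_i: float, g_j: float) -> float:
    """RS when only the signal is gain-scaled (``u = gS + N``).

    ``rho = g_i g_j sigma_s^2 / sqrt((g_i^2 sigma_s^2 + sigma_n^2)(g_j^2 sigma_s^2 + sigma_n^2))``.
    Large gains suppress the relative noise contribution, so rho -> 1 as
    both gains grow.  A zero gain with nonzero noise gives the limit 0.
    """
    d_i = g_i**2 * sigma_s**2 + sigma_n**2
    d_j = g_j**2 * sigma_s**2 + sigma_n**2
    if d_i <= 0 or d_j <= 0:
        raise DegenerateInputError("rs_signal_scaled undefined: zero variance")
    return g_i * g_j * sigma_s**2 / np.sqrt(d_i * d_j)


def rs_both_scaled(sigma_s: float, sigma_n: float, g_i: float, g_j: float) -> float:
    """RS when both signal and noise share the gain (``u = gS + gN``).

    The gain cancels from the correlation, so this equals
    :func:`rs_unscaled` for any positive gains.
    """
    if g_i <= 0 or g_j <= 0:
        raise DegenerateInputError("gains must be positive")
    return rs_unscaled(sigma_s, sigma_n)


def rs_independent(
    sigma_s: float,
    sigma_t: float,
    sigma_n: float,
    beta_i: float,
    beta_j: float,
) -> float:
    """RS of the independent-mixing model ``u = S_S + N + beta*T_B``.

    The behavioural signal beta*T_B is frozen in its tuning T_B but
    scaled by the per-repeat behavioural parameter beta; from the
    stimulus point of view it acts as extra noise:

    ``rho = sigma_s^2 / sqrt((sigma_s^2 + beta_i^2 sigma_t^2 + sigma_n^2)
    (sigma_s^2 + beta_j^2 sigma_t^2 + sigma_n^2))``.

    With ``beta_i = beta_j = beta`` this reduces to
    ``sigma_s^2 / (sigma_s^2 + sigma_b^2 + sigma_n^2)`` with
    ``sigma_b = beta * sigma_t``.
    """
    d_i = sigma_s**2 + beta_i**2 * sigma_t**2 + sigma_n**2
    d_j = sigma_s**2 + beta_j**2 * sigma_t**2 + sigma_n**2
    if d_i <= 0 or d_j <= 0:
        raise DegenerateInputError("rs_independent undefined: zero variance")
    return sigma_s**2 / np.sqrt(d_i * d_j)


def rs_independent_frozen_tuning(
    sigma_s: float,
    sigma_t: float,
    sigma_n: float,
    beta_i: float,
    beta_j: float,
) -> float:
    """RS of the independent model when the behavioural tuning is frozen.

    If the tuning vector T_B is the same on both repeats (only the
    behavioural amplitude beta changes), the behavioural pattern is a
    shared component and enters the covariance as well:

    ``rho = (sigma_s^2 + beta_i beta_j sigma_t^2) /
    sqrt((sigma_s^2 + beta_i^2 sigma_t^2 + sigma_n^2)
    (sigma_s^2 + beta_j^2 sigma_t^2 + sigma_n^2))``.

    :func:`rs_independent` is the marginal, stimulus-part view of the
    same model (behavioural signal counted as noise); this form is the
    expectation of the raw repeat-pair correlation when T_B persists.
    """
    d_i = sigma_s**2 + beta_i**2 * sigma_t**2 + sigma_n**2
    d_j = sigma_s**2 + beta_j**2 * sigma_t**2 + sigma_n**2
    if d_i <= 0 or d_j <= 0:
        raise DegenerateInputError("undefined: zero variance")
    return (sigma_s**2 + beta_i * beta_j * sigma_t**2) / np.sqrt(d_i * d_j)


def rs_baseline_dominated(var_baseline: float, var_modulation: float) -> float:
    """Population RS when per-unit baselines carry the similarity.

    For responses ``r = r_b + r_m`` with baselines r_b fixed across
    repeats and the modulation r_m redrawn independently on every
    repeat, each unit has stimulus reliability zero, yet the raw
    population vectors share the baseline component:

    ``rho = Var(r_b) / (Var(r_b) + Var(r_m))``.

    As the modulation vanishes relative to the baseline spread the
    population RS approaches 1 even though no unit is reliable.
    """
    denom = var_baseline + var_modulation
    if denom <= 0:
        raise DegenerateInputError("undefined for zero total variance")
    return var_baseline / denom
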