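"""Repeat-level generative models of stimulus/behaviour mixing.

Abstract models of how a behavioural state variable shapes the
population response to repeated presentations of the same stimulus:

* gain models ``u = gS + gN`` / ``u = S + gN`` / ``u = gS + N`` — a
  per-repeat gain g scales the frozen stimulus signal S and/or the
  per-repeat noise N;
* an extended gain model with an explicit stimulus dimension and
  per-unit stimulus tuning (``u_k = g T_k s + N``);
* an independent-mixing model ``u = S_S + N + beta T_B`` in which the
  behavioural signal adds to the response instead of scaling it.

Each simulator returns a :class:`RepeatResponses` record carrying the
responses together with the ground-truth draws, so that analysis code
and the closed-form theory in :mod:`driftlab.theory` can be checked
against one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "GainModelParams",
    "ExtendedGainParams",
    "IndependentModelParams",
    "RepeatResponses",
    "simulate_gain_model",
    "simulate_extended_gain",
    "simulate_independent",
    "rs_vs_relative_behavior",
    "repeat_rs_matrix",
    "unit_reliability",
    "unit_behavior_modulation",
    "reliability_modulation_regression",
]

GainVariant = Literal["both", "signal", "noise"]


def _check_positive(name: str, value: float) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class GainModelParams:
    """Parameters of the single-stimulus gain models.

    Defaults follow the reference configuration: 1000 units, 100
    repeats, uniform [0, 1] signal and noise, gains uniform on
    [0.5, 2].
    """

    n_units: int = 1000
    n_repeats: int = 100
    gain_range: tuple[float, float] = (0.5, 2.0)
    variant: GainVariant = "both"
    signal_range: tuple[float, float] = (0.0, 1.0)
    noise_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2 or self.n_repeats < 2:
            raise ValueError("need at least 2 units and 2 repeats")
        if self.gain_range[0] <= 0 or self.gain_range[1] < self.gain_range[0]:
            raise ValueError("gain_range must be positive and ordered")
        if self.variant not in ("both", "signal", "noise"):
            raise ValueError(f"unknown gain variant {self.variant!r}")


@dataclass(frozen=True)
class ExtendedGainParams:
    """Signal-gain model with an Ns-dimensional stimulus and per-unit tuning."""

    n_units: int = 1000
    n_repeats: int = 200
    n_stimuli: int = 10
    gain_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stimuli < 2:
            raise ValueError("need at least 2 stimulus values")
        if self.n_units < 2 or self.n_repeats < 2:
            raise ValueError("need at least 2 units and 2 repeats")


@dataclass(frozen=True)
class IndependentModelParams:
    """Independent-mixing model ``u = S_S + N + beta T_B``.

    ``noise_scale`` and ``behavior_scale`` implement the x1.5-noise and
    x0.5-behaviour variants; ``n_stimuli`` switches on an explicit
    stimulus dimension (per-unit tuning ``T_k s``, as in the extended
    gain model) so that unit-level stimulus reliability is defined.
    ``refresh_tuning`` redraws the behavioural tuning vector on every
    repeat, the regime in which the behavioural signal is pure noise
    from the stimulus point of view.
    """

    n_units: int = 1000
    n_repeats: int = 100
    beta_range: tuple[float, float] = (0.5, 2.0)
    tuning_range: tuple[float, float] = (0.0, 1.0)
    noise_scale: float = 1.0
    behavior_scale: float = 1.0
    n_stimuli: int | None = None
    refresh_tuning: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2 or self.n_repeats < 2:
            raise ValueError("need at least 2 units and 2 repeats")
        _check_positive("noise_scale", self.noise_scale)
        if self.behavior_scale < 0:
            raise ValueError("behavior_scale must be non-negative")


@dataclass
class RepeatResponses:
    """Population responses to repeated stimulus presentations.

    ``responses`` has shape (Nr, Np) or (Nr, Np, Ns); ``behavior``
    holds the per-repeat gain g or behavioural amplitude beta.
    """

    responses: np.ndarray
    behavior: np.ndarray
    signal: np.ndarray
    tuning: np.ndarray | None = None
    behavior_tuning: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_repeats(self) -> int:
        return self.responses.shape[0]

    @property
    def n_units(self) -> int:
        return self.responses.shape[1]

    def flat_responses(self) -> np.ndarray:
        """Responses with any stimulus axis folded into the feature axis."""
        return self.responses.reshape(self.n_repeats, -1)


def simulate_gain_model(params: GainModelParams) -> RepeatResponses:
    """Simulate the single-stimulus gain model.

    The signal vector S is drawn once and frozen across repeats; the
    noise N and the gain g are redrawn on each repeat.  The variant
    selects which components the gain multiplies.
    """
    rng = np.random.default_rng(params.seed)
    lo_s, hi_s = params.signal_range
    lo_n, hi_n = params.noise_range
    signal = rng.uniform(lo_s, hi_s, size=params.n_units)
    gains = rng.uniform(*params.gain_range, size=params.n_repeats)
    noise = rng.uniform(lo_n, hi_n, size=(params.n_repeats, params.n_units))
    g = gains[:, None]
    if params.variant == "both":
        responses = g * signal[None, :] + g * noise
    elif params.variant == "signal":
        responses = g * signal[None, :] + noise
    else:  # noise
        responses = signal[None, :] + g * noise
    return RepeatResponses(
        responses=responses,
        behavior=gains,
        signal=signal,
        meta={"model": "gain", "variant": params.variant},
    )


def simulate_extended_gain(params: ExtendedGainParams) -> RepeatResponses:
    """Simulate the extended signal-gain model with stimulus tuning.

    Unit k responds to stimulus value s with ``g * T_k * s + N``; the
    stimulus vector s (length Ns) and the tuning T are frozen, the
    noise is redrawn per stimulus and repeat, and the gain per repeat.
    """
    rng = np.random.default_rng(params.seed)
    stimulus = rng.uniform(0, 1, size=params.n_stimuli)
    tuning = rng.uniform(0, 1, size=params.n_units)
    gains = rng.uniform(*params.gain_range, size=params.n_repeats)
    noise = rng.uniform(
        0, 1, size=(params.n_repeats, params.n_units, params.n_stimuli)
    )
    signal = tuning[:, None] * stimulus[None, :]  # Np x Ns
    responses = gains[:, None, None] * signal[None, :, :] + noise
    return RepeatResponses(
        responses=responses,
        behavior=gains,
        signal=signal,
        tuning=tuning,
        meta={"model": "extended_gain"},
    )


def simulate_independent(params: IndependentModelParams) -> RepeatResponses:
    """Simulate the independent-mixing model ``u = S_S + N + beta T_B``.

    The stimulus signal is frozen across repeats, the noise is redrawn
    per repeat (scaled by ``noise_scale``), and the behavioural signal
    is the tuning vector T_B scaled by the per-repeat amplitude beta
    and ``behavior_scale``.
    """
    rng = np.random.default_rng(params.seed)
    np_, nr = params.n_units, params.n_repeats
    if params.n_stimuli is None:
        signal = rng.uniform(0, 1, size=np_)
        tuning = None
        shape = (nr, np_)
    else:
        stimulus = rng.uniform(0, 1, size=params.n_stimuli)
        tuning = rng.uniform(0, 1, size=np_)
        signal = tuning[:, None] * stimulus[None, :]  # Np x Ns
        shape = (nr, np_, params.n_stimuli)
    betas = rng.uniform(*params.beta_range, size=nr)
    behavior_tuning = rng.uniform(*params.tuning_range, size=np_)
    noise = params.noise_scale * rng.uniform(0, 1, size=shape)
    if params.refresh_tuning:
        tb = rng.uniform(*params.tuning_range, size=(nr, np_))
    else:
        tb = np.broadcast_to(behavior_tuning, (nr, np_))
    sb = params.behavior_scale * betas[:, None] * tb  # Nr x Np
    if params.n_stimuli is None:
        responses = signal[None, :] + noise + sb
    else:
        responses = signal[None, :, :] + noise + sb[:, :, None]
    return RepeatResponses(
        responses=responses,
        behavior=betas,
        signal=signal,
        tuning=tuning,
        behavior_tuning=behavior_tuning,
        meta={"model": "independent", "refresh_tuning": params.refresh_tuning},
    )


def repeat_rs_matrix(responses: RepeatResponses) -> np.ndarray:
    """Pearson correlation matrix between repeat population vectors."""
    return np.corrcoef(responses.flat_responses())


def rs_vs_relative_behavior(
    responses: RepeatResponses, n_bins: int = 20
) -> dict[str, np.ndarray]:
    """Representational similarity against the relative behavioural parameter.

    Every unordered repeat pair contributes two points, (b_i/b_j, rho)
    and (b_j/b_i, rho), producing the symmetric scatter around a
    relative parameter of 1; a linearly binned average curve (default
    20 bins over the observed range) summarizes it.
    """
    if responses.n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    rho = repeat_rs_matrix(responses)
    b = responses.behavior
    iu, ju = np.triu_indices(responses.n_repeats, k=1)
    ratios = np.concatenate([b[iu] / b[ju], b[ju] / b[iu]])
    sims = np.concatenate([rho[iu, ju], rho[iu, ju]])
    edges = np.linspace(ratios.min(), ratios.max(), n_bins + 1)
    idx = np.clip(np.digitize(ratios, edges) - 1, 0, n_bins - 1)
    bin_means = np.full(n_bins, np.nan)
    for k in range(n_bins):
        mask = idx == k
        if mask.any():
            bin_means[k] = sims[mask].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {
        "relative_behavior": ratios,
        "rs": sims,
        "bin_centers": centers,
        "bin_means": bin_means,
        "bin_edges": edges,
    }


def unit_reliability(responses: RepeatResponses) -> np.ndarray:
    """Per-unit stimulus reliability for models with a stimulus axis.

    Mean Pearson correlation of a unit's Ns-length stimulus-response
    vector over all unordered repeat pairs.
    """
    u = responses.responses
    if u.ndim != 3:
        raise ValueError("unit reliability requires a stimulus dimension")
    nr, np_, _ = u.shape
    centered = u - u.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2)
    # corr between repeats i,j per unit: sum_s c_i c_j / (|c_i||c_j|)
    out = np.empty(np_)
    for k in range(np_):
        c = centered[:, k, :]
        cov = c @ c.T
        denom = np.outer(norms[:, k], norms[:, k])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / denom
        iu, ju = np.triu_indices(nr, k=1)
        out[k] = np.nanmean(corr[iu, ju])
    return out


def unit_behavior_modulation(responses: RepeatResponses) -> np.ndarray:
    """Correlation of each unit's per-repeat response with the behavioural parameter.

    For stimulus-resolved responses the per-repeat response is first
    averaged over the stimulus axis.
    """
    u = responses.flat_responses() if responses.responses.ndim == 2 else (
        responses.responses.mean(axis=2)
    )
    b = responses.behavior
    bc = b - b.mean()
    uc = u - u.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(uc, axis=0) * np.linalg.norm(bc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (uc.T @ bc) / denom


def reliability_modulation_regression(
    responses: RepeatResponses,
) -> dict[str, float]:
    """OLS of stimulus reliability on |behavioural modulation| across units.

    The gain model's signature is a strong positive relation (strongly
    tuned units are also strongly gain-modulated); the independent
    model predicts none.
    """
    rel = unit_reliability(responses)
    mod = np.abs(unit_behavior_modulation(responses))
    mask = np.isfinite(rel) & np.isfinite(mod)
    x, y = mod[mask], rel[mask]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {"slope": float(slope), "intercept": float(intercept), "r2": r2}
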