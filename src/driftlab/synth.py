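"""Synthetic recording sessions with known ground truth.

The generator emulates the statistical structure the drift analyses
assume: two blocks of a 30-s natural movie (M one-second frames,
several repeats per block) separated by a gap of other activity,
per-unit baseline rates ("setpoints"), frozen per-unit stimulus tuning
curves, signed behavioural tuning, Poisson (or Gaussian) count noise,
and a slowly drifting latent arousal state beta(t) that drives both
pupil width and running speed.

The latent state follows an Ornstein-Uhlenbeck process (default
timescale 60 s, stationary SD 1) with an optional deterministic offset
in the second block, mimicking the abrupt arousal transitions seen
between presentation blocks.  Mixing regimes:

``independent``
    rate = rb + A*f(frame) + TB*beta   (behaviour adds)
``gain_signal``
    rate = rb + g(beta)*A*f(frame)
``gain_noise``
    rate = g(beta)*rb + A*f(frame)  (the untuned component is scaled;
    under Gaussian noise the additive noise SD is scaled instead)
``gain_both``
    rate = g(beta)*(rb + A*f(frame))

with gain link g(beta) = exp(kappa*beta), kappa chosen so g spans
roughly [0.5, 2] over typical beta.  Rates are clipped at 0 before
sampling, a documented bias source at extreme parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .session import Session

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_behavior",
    "simulate_session",
    "make_fixture_suite",
    "strong_tuning_config",
]

logger = logging.getLogger(__name__)

Regime = Literal["independent", "gain_signal", "gain_noise", "gain_both"]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic session.

    Stimulus structure defaults to a dataset-1-like layout: 2 blocks of
    10 repeats of a 30-frame movie, separated by a gap.  Rates are in
    counts per 1-s bin.
    """

    n_units: int = 200
    n_frames: int = 30
    repeats_per_block: int = 10
    n_blocks: int = 2
    gap_bins: int = 120
    edge_bins: int = 30  # pre/post padding outside stimulus blocks
    regime: Regime = "independent"
    # latent behavioural state
    ou_timescale: float = 60.0  # s
    ou_sd: float = 0.5
    block_offsets: tuple[float, ...] = (0.0, 1.5)
    # behaviour observation model
    pupil_noise_sd: float = 0.1
    running_gain: float = 10.0  # cm/s per unit of beta
    running_noise_sd: float = 2.0
    # unit parameters
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 0.7
    stim_modulation_mean: float = 0.5  # exponential mean of modulation index
    stim_modulation_max: float = 1.2  # cap keeps additive tuning non-negative
    behavior_tuning_scale: float = 0.8  # TB magnitude relative to baseline
    behavior_positive_fraction: float = 0.9
    behavior_negative_attenuation: float = 0.3
    gain_kappa: float = 0.35  # exp link: g spans ~[0.5, 2] for beta in +-2
    noise_model: Literal["poisson", "gaussian"] = "poisson"
    gaussian_noise_sd: float = 1.0
    stimulus_name: str = "natural_movie_1"
    second_stimulus: str | None = None  # e.g. drifting_gratings block pair

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_frames < 2:
            raise ValueError("need >=1 unit and >=2 frames")
        if self.repeats_per_block < 1 or self.n_blocks < 1:
            raise ValueError("repeats_per_block and n_blocks must be >=1")
        if self.ou_timescale <= 0 or self.ou_sd < 0:
            raise ValueError("OU parameters must be positive")
        if self.regime not in (
            "independent",
            "gain_signal",
            "gain_noise",
            "gain_both",
        ):
            raise ValueError(f"unknown regime {self.regime!r}")
        if len(self.block_offsets) < self.n_blocks:
            raise ValueError("need a block offset per block")
        if self.second_stimulus is not None and self.n_blocks != 2:
            raise ValueError("second_stimulus requires exactly 2 blocks")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "block_offsets" in d:
            d["block_offsets"] = tuple(d["block_offsets"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent parameters behind a synthetic session."""

    baseline: np.ndarray  # rb per unit, counts/bin
    stim_tuning: np.ndarray  # units x frames additive tuning A*f
    behavior_tuning: np.ndarray  # TB per unit, signed
    noise_scale: np.ndarray  # per-unit noise SD (gaussian) or sqrt(rate) proxy
    beta: np.ndarray  # latent state per bin
    regime: str
    config: SynthConfig | None = None


def _session_timeline(config: SynthConfig) -> tuple[int, pd.DataFrame]:
    """Build the epoch table and total bin count.

    Layout: edge | block1 | gap | block2 | ... | edge, with each block
    holding repeats_per_block back-to-back movie repeats.  If
    ``second_stimulus`` is set, the gap hosts two blocks of that
    stimulus (same frame/repeat structure), both under the pre-step
    behavioural state.
    """
    rows = []
    t = config.edge_bins
    block_len = config.repeats_per_block * config.n_frames
    for b in range(config.n_blocks):
        for r in range(config.repeats_per_block):
            for m in range(config.n_frames):
                rows.append((config.stimulus_name, b, r, m, t))
                t += 1
        if b < config.n_blocks - 1:
            if config.second_stimulus is not None:
                # two blocks of the second stimulus inside the gap, so
                # they share one behavioural state epoch
                pad = max((config.gap_bins - 2 * block_len) // 3, 5)
                for gb in range(2):
                    t += pad
                    for r in range(config.repeats_per_block):
                        for m in range(config.n_frames):
                            rows.append((config.second_stimulus, gb, r, m, t))
                            t += 1
                t += pad
            else:
                t += config.gap_bins
    t += config.edge_bins
    epochs = pd.DataFrame(
        rows, columns=["stimulus_name", "block", "repeat", "frame", "bin"]
    )
    return t, epochs


def _ou_trace(
    n_bins: int, timescale: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path sampled at 1-s bins."""
    if sd == 0:
        return np.zeros(n_bins)
    alpha = np.exp(-1.0 / timescale)
    innov_sd = sd * np.sqrt(1 - alpha**2)
    x = np.empty(n_bins)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, size=n_bins - 1)
    for t in range(1, n_bins):
        x[t] = alpha * x[t - 1] + eps[t - 1]
    return x


def _block_offset_trace(
    config: SynthConfig, n_bins: int, epochs: pd.DataFrame
) -> np.ndarray:
    """Deterministic beta offset switching at each movie-block onset."""
    offset = np.full(n_bins, config.block_offsets[0])
    movie = epochs[epochs["stimulus_name"] == config.stimulus_name]
    for b in range(1, config.n_blocks):
        onset = int(movie.loc[movie["block"] == b, "bin"].min())
        offset[onset:] = config.block_offsets[b]
    return offset


def simulate_behavior(
    config: SynthConfig, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate the behaviour trace and the latent state driving it.

    Pupil width is an affine map of beta plus Gaussian observation
    noise; running speed is a rectified linear map of beta plus noise
    (non-negative).  Returns ``(behavior, beta)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    n_bins, epochs = _session_timeline(config)
    beta = _ou_trace(n_bins, config.ou_timescale, config.ou_sd, rng)
    beta = beta + _block_offset_trace(config, n_bins, epochs)
    pupil = beta + rng.normal(0, config.pupil_noise_sd, size=n_bins)
    running = np.maximum(
        0.0,
        config.running_gain * beta
        + rng.normal(0, config.running_noise_sd, size=n_bins),
    )
    behavior = pd.DataFrame(
        {
            "pupil_width": pupil,
            "pupil_x": np.zeros(n_bins),
            "pupil_y": np.zeros(n_bins),
            "running_speed": running,
        }
    )
    return behavior, beta


def _psth_curves(
    n_units: int, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-SD frame-tuning curves with PSTH-like skew.

    Rectified Gaussian bumps (sparse positive transients over a silent
    background) standardized per unit, so the additive tuning rarely
    drives the expected rate negative.
    """
    raw = np.maximum(rng.standard_normal((n_units, n_frames)), 0.0)
    raw -= raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    return raw / np.where(sd > 0, sd, 1.0)


def _draw_units(config: SynthConfig, rng: np.random.Generator):
    """Per-unit baseline, additive frame tuning and behavioural tuning."""
    rb = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                       size=config.n_units)
    # frame tuning: zero-mean unit-SD curve scaled by rb * modulation index
    mod_index = np.minimum(
        rng.exponential(config.stim_modulation_mean, size=config.n_units),
        config.stim_modulation_max,
    )
    curves = _psth_curves(config.n_units, config.n_frames, rng)
    stim_tuning = (rb * mod_index)[:, None] * curves
    # behavioural tuning scales with baseline, mostly positive
    signs = np.where(
        rng.uniform(size=config.n_units) < config.behavior_positive_fraction,
        1.0,
        -1.0,
    )
    # moderate spread of arousal coupling: gamma(4, 1/4), mean 1, SD 1/2;
    # arousal-suppressed units couple more weakly than facilitated ones
    magnitude = rng.gamma(4.0, 0.25, size=config.n_units)
    magnitude = np.where(
        signs < 0, config.behavior_negative_attenuation * magnitude, magnitude
    )
    tb = config.behavior_tuning_scale * rb * magnitude * signs
    return rb, stim_tuning, tb


def simulate_session(
    config: SynthConfig, seed: int
) -> tuple[Session, GroundTruth]:
    """Generate a full synthetic session plus its ground truth.

    Per-bin expected rate combines baseline, frame tuning during
    stimulus epochs and the behavioural term according to the mixing
    regime; counts are then drawn from the configured noise model with
    rates clipped at zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    behavior, beta = simulate_behavior(config, seed)
    n_bins, epochs = _session_timeline(config)
    rb, stim_tuning, tb = _draw_units(config, rng)

    stim = np.zeros((config.n_units, n_bins))
    for stim_name in epochs["stimulus_name"].unique():
        sel = epochs[epochs["stimulus_name"] == stim_name]
        # independent frozen tuning per stimulus type; the movie keeps
        # the primary curve, any second stimulus gets its own
        if stim_name == config.stimulus_name:
            tuning = stim_tuning
        else:
            curves = _psth_curves(config.n_units, config.n_frames, rng)
            amp = np.abs(stim_tuning).max(axis=1)
            tuning = amp[:, None] * curves
        stim[:, sel["bin"].to_numpy()] = tuning[:, sel["frame"].to_numpy()]

    g = np.exp(config.gain_kappa * beta)[None, :]
    if config.regime == "independent":
        rate = rb[:, None] + stim + tb[:, None] * beta[None, :]
    elif config.regime == "gain_signal":
        rate = rb[:, None] + g * stim
    elif config.regime == "gain_noise":
        if config.noise_model == "gaussian":
            rate = rb[:, None] + stim
        else:
            rate = g * rb[:, None] + stim
    else:  # gain_both
        rate = g * (rb[:, None] + stim)

    neg_frac = float((rate < 0).mean())
    rate_clipped = np.clip(rate, 0.0, None)
    if config.noise_model == "poisson":
        counts = rng.poisson(rate_clipped).astype(float)
        noise_scale = np.sqrt(rb)
    else:
        sd = config.gaussian_noise_sd
        noise = rng.normal(0, sd, size=rate.shape)
        if config.regime == "gain_noise":
            noise = noise * g
        counts = np.clip(rate_clipped + noise, 0.0, None)
        noise_scale = np.full(config.n_units, sd)
    if neg_frac > 0.10:
        msg = f"{neg_frac:.1%} of expected rates were negative before clipping"
        logger.warning(msg)
        if config.noise_model == "gaussian":
            warnings.warn(msg, RuntimeWarning, stacklevel=2)

    units = pd.DataFrame(
        {
            "unit_id": [f"u{i:04d}" for i in range(config.n_units)],
            "region": ["V1"] * config.n_units,
        }
    )
    session = Session(
        units=units,
        counts=counts,
        behavior=behavior,
        epochs=epochs,
        meta={"generator": "driftlab.synth", "seed": int(seed),
              "regime": config.regime},
    ).validate()
    truth = GroundTruth(
        baseline=rb,
        stim_tuning=stim_tuning,
        behavior_tuning=tb,
        noise_scale=noise_scale,
        beta=beta,
        regime=config.regime,
        config=config,
    )
    return session, truth


def strong_tuning_config(**overrides) -> SynthConfig:
    """Config with strong behavioural tuning for decoding analyses.

    More units and a stronger, less noisy coupling of activity to the
    latent state, the regime in which behaviour should be decodable
    from the population with high held-out accuracy.
    """
    base = dict(
        n_units=200,
        behavior_tuning_scale=1.0,
        pupil_noise_sd=0.05,
        running_noise_sd=1.0,
        block_offsets=(0.0, 1.5),
    )
    base.update(overrides)
    return SynthConfig(**base)


def make_fixture_suite(seed: int) -> dict[str, tuple[Session, GroundTruth]]:
    """Deterministic named fixture sessions for tests and examples.

    ``dataset1-like``: 2 blocks x 10 repeats x 30 frames;
    ``dataset2-like``: 2 blocks x 30 repeats; ``gratings+movie``: a
    movie plus a drifting-grating block pair in the gap.
    """
    ss = np.random.SeedSequence(int(seed))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    configs = {
        "dataset1-like": SynthConfig(repeats_per_block=10),
        "dataset2-like": SynthConfig(repeats_per_block=30),
        "gratings+movie": SynthConfig(
            repeats_per_block=10,
            second_stimulus="drifting_gratings",
            gap_bins=400,
        ),
    }
    return {
        name: simulate_session(cfg, s)
        for (name, cfg), s in zip(configs.items(), seeds)
    }
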