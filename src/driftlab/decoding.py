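"""Linear frame decoding with out-of-distribution d-prime evaluation.

A ridge-regularized linear readout is trained per target movie frame
on block-1 population responses (label 1 for the target frame, 0
otherwise) and evaluated on block 2 via the discriminability

``d' = (mu_s - mu_n) / sqrt(sigma_s^2 + sigma_n^2)``

where the signal statistics are the readout value's mean/SD over
block-2 repeats of the target frame and the noise statistics over
repeats of the test frame.  The readout value D is used as the
continuous pre-threshold score: a thresholded 0/1 decision would make
the mean/SD statistics degenerate.

The module also selects reliable units, trains behaviour (pupil /
running) decoders on a random half of repeats, and runs the
sensory-bias check on the behaviour-decoder weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import RepeatTensor

__all__ = [
    "DecoderModel",
    "DprimeMatrix",
    "train_frame_decoder",
    "dprime_matrix",
    "select_reliable_units",
    "train_behavior_decoder",
    "sensory_bias_check",
]

logger = logging.getLogger(__name__)

MIN_RELIABLE_UNITS = 10  # session-inclusion rule for reliable-unit analyses


@dataclass
class DecoderModel:
    """One ridge readout per target frame.

    ``weights`` is (M, N): row m holds the readout for target frame m;
    ``bias`` its intercepts.  Inputs are z-scored per unit with the
    training statistics stored in ``input_mean`` / ``input_sd``.
    """

    weights: np.ndarray
    bias: np.ndarray
    ridge: float
    input_mean: np.ndarray
    input_sd: np.ndarray
    training_block: int | None = None

    def readout(self, responses: np.ndarray) -> np.ndarray:
        """Continuous readout values D for (samples x N) responses."""
        x = (responses - self.input_mean) / self.input_sd
        return x @ self.weights.T + self.bias


@dataclass
class DprimeMatrix:
    """d' between all (target, test) frame combinations.

    ``dprime[m, m']`` is the discriminability of target frame m against
    test frame m' in the held-out block; the diagonal is NaN.
    """

    dprime: np.ndarray
    mu_signal: np.ndarray
    sd_signal: np.ndarray

    def mean_off_diagonal(self) -> float:
        m = self.dprime.shape[0]
        mask = ~np.eye(m, dtype=bool)
        return float(np.nanmean(self.dprime[mask]))


def _tensor_samples(tensor: RepeatTensor) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a tensor to (R*M, N) samples with frame labels."""
    x = tensor.data.transpose(0, 2, 1).reshape(-1, tensor.n_units)
    frames = np.tile(np.arange(tensor.n_frames), tensor.n_repeats)
    return x, frames


def _ridge_solve(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form ridge for multi-target y; returns (weights, bias)."""
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    xc = x - xm
    yc = y - ym
    n_features = x.shape[1]
    gram = xc.T @ xc + lam * np.eye(n_features)
    w = np.linalg.solve(gram, xc.T @ yc)  # N x targets
    b = ym - xm @ w
    return w.T, b


def train_frame_decoder(
    tensor: RepeatTensor, ridge: float = 1.0
) -> DecoderModel:
    """Fit per-frame ridge readouts on a training-block tensor.

    Each sample is one repeat's population response to one frame;
    inputs are z-scored per unit over the training samples.  Target
    labels are 1 for the target frame and 0 elsewhere.  A
    non-positive ridge on singular data is bumped to a minimal value
    with a warning.
    """
    if tensor.n_repeats < 2 or tensor.n_frames < 2:
        raise ValueError("need >=2 repeats and >=2 frames to train")
    x, frames = _tensor_samples(tensor)
    if ridge <= 0:
        if x.shape[0] <= x.shape[1]:
            logger.warning("singular design without regularization; "
                           "forcing ridge=1e-8")
            ridge = 1e-8
        else:
            ridge = 0.0
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xz = (x - mean) / sd
    labels = (frames[:, None] == np.arange(tensor.n_frames)[None, :]).astype(
        float
    )
    w, b = _ridge_solve(xz, labels, ridge)
    block = int(tensor.blocks[0]) if len(np.unique(tensor.blocks)) == 1 else None
    return DecoderModel(
        weights=w, bias=b, ridge=float(ridge), input_mean=mean, input_sd=sd,
        training_block=block,
    )


def dprime_matrix(
    model: DecoderModel,
    tensor: RepeatTensor,
    pool_nontargets: bool = False,
) -> DprimeMatrix:
    """Evaluate a trained decoder on a held-out block.

    For each target frame m, the readout D is computed for every
    repeat of every frame.  ``d'(m, m') = (mu_s - mu_n) /
    sqrt(sigma_s^2 + sigma_n^2)`` with signal statistics over repeats
    of frame m and noise statistics over repeats of test frame m'
    (or pooled over all non-target frames when ``pool_nontargets``).
    Zero pooled variance yields +-inf, flagged by a logged warning.
    """
    if tensor.n_repeats < 2:
        raise ValueError("need >=2 repeats in the evaluation block")
    m = tensor.n_frames
    # readout per repeat and frame: (R, M_frames, M_targets)
    d = np.stack(
        [model.readout(tensor.data[r].T) for r in range(tensor.n_repeats)]
    )
    mu = d.mean(axis=0)  # M_frames x M_targets
    sd = d.std(axis=0, ddof=1)
    mu_s = np.array([mu[t, t] for t in range(m)])
    sd_s = np.array([sd[t, t] for t in range(m)])
    out = np.full((m, m), np.nan)
    for target in range(m):
        for test in range(m):
            if test == target:
                continue
            if pool_nontargets:
                mask = np.arange(m) != target
                vals = d[:, mask, target].ravel()
                mu_n, sd_n = vals.mean(), vals.std(ddof=1)
            else:
                mu_n = mu[test, target]
                sd_n = sd[test, target]
            denom = np.sqrt(sd_s[target] ** 2 + sd_n**2)
            if denom == 0:
                logger.warning("zero pooled variance: infinite d'")
                out[target, test] = np.inf if mu_s[target] > mu_n else -np.inf
            else:
                out[target, test] = (mu_s[target] - mu_n) / denom
    return DprimeMatrix(dprime=out, mu_signal=mu_s, sd_signal=sd_s)


def select_reliable_units(
    reliability: pd.DataFrame,
    threshold: float = 0.5,
    by: str = "reliability",
) -> dict:
    """Select units whose reliability (or |behavioural modulation|) exceeds a threshold.

    ``by='reliability'`` keeps units with stimulus reliability above
    ``threshold`` (default 0.5); ``by`` may name any numeric column
    (e.g. an absolute behavioural-modulation column) for the
    contrast analyses.  A session qualifies for reliable-unit decoding
    comparisons only with more than 10 selected units.
    """
    if by not in reliability.columns:
        raise KeyError(f"column {by!r} not in reliability record")
    vals = reliability[by].to_numpy(dtype=float)
    mask = np.isfinite(vals) & (vals > threshold)
    if not mask.any():
        logger.warning("no units pass %s > %s", by, threshold)
    return {
        "mask": mask,
        "unit_ids": reliability.loc[mask, "unit_id"].to_numpy(),
        "n_selected": int(mask.sum()),
        "session_included": bool(mask.sum() > MIN_RELIABLE_UNITS),
    }


def subset_tensor(tensor: RepeatTensor, mask: np.ndarray) -> RepeatTensor:
    """Restrict a tensor to a unit subset."""
    if mask.dtype != bool or len(mask) != tensor.n_units:
        raise ValueError("boolean unit mask required")
    if not mask.any():
        raise ValueError("empty unit subset")
    return RepeatTensor(
        data=tensor.data[:, mask, :],
        blocks=tensor.blocks,
        unit_ids=tensor.unit_ids[mask],
        stimulus_name=tensor.stimulus_name,
        bins=tensor.bins,
    )


def train_behavior_decoder(
    tensor: RepeatTensor,
    behavior_by_bin: dict[str, np.ndarray],
    ridge: float = 1.0,
    split_seed: int = 0,
) -> dict:
    """Ridge-decode behaviour traces from population activity.

    Repeats are split at random into training and test halves (seeded);
    a ridge regression maps each bin's z-scored population response to
    each behavioural target (e.g. pupil width, running speed).  Reports
    the Pearson correlation between predicted and actual traces on the
    held-out repeats.
    """
    if tensor.n_repeats < 4:
        raise ValueError("need >=4 repeats for a half split")
    if tensor.bins is None:
        raise ValueError("tensor carries no bin indices")
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(tensor.n_repeats)
    half = tensor.n_repeats // 2
    train_reps, test_reps = order[:half], order[half:]

    def stack(reps: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        x = tensor.data[reps].transpose(0, 2, 1).reshape(-1, tensor.n_units)
        bins = tensor.bins[reps].ravel()
        targets = {k: np.asarray(v, float)[bins] for k, v in
                   behavior_by_bin.items()}
        return x, targets

    x_tr, y_tr = stack(train_reps)
    x_te, y_te = stack(test_reps)
    mean = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    names = list(behavior_by_bin)
    y_mat = np.column_stack([y_tr[k] for k in names])
    w, b = _ridge_solve((x_tr - mean) / sd, y_mat, ridge)
    pred = ((x_te - mean) / sd) @ w.T + b
    out = {"weights": w, "bias": b, "targets": names,
           "train_repeats": train_reps, "test_repeats": test_reps,
           "input_mean": mean, "input_sd": sd, "correlations": {}}
    for i, k in enumerate(names):
        actual = y_te[k]
        valid = np.isfinite(actual) & np.isfinite(pred[:, i])
        if actual[valid].std() == 0 or pred[valid, i].std() == 0:
            out["correlations"][k] = np.nan
        else:
            out["correlations"][k] = float(
                np.corrcoef(pred[valid, i], actual[valid])[0, 1]
            )
    return out


def sensory_bias_check(
    weights: np.ndarray,
    tensor: RepeatTensor,
    input_mean: np.ndarray | None = None,
    input_sd: np.ndarray | None = None,
) -> dict:
    """Cross-repeat correlation of behaviour-decoder readout traces.

    Each repeat's N x M response is projected onto the behaviour-
    decoder weights, giving an M-length readout trace per repeat.  A
    systematic sensory bias of the behavioural readout would show as
    positive correlation of these traces across repeats; independence
    of stimulus and behaviour predicts correlations near zero.
    """
    if tensor.n_repeats < 2:
        raise ValueError("need >=2 repeats")
    w = np.asarray(weights, dtype=float).ravel()
    if len(w) != tensor.n_units:
        raise ValueError("weights not aligned with tensor units")
    data = tensor.data
    if input_mean is not None:
        sd = np.where(input_sd > 0, input_sd, 1.0)
        data = (data - input_mean[None, :, None]) / sd[None, :, None]
    traces = np.einsum("rnm,n->rm", data, w)
    sd_t = traces.std(axis=1)
    if (sd_t == 0).all():
        raise ValueError("constant projected traces")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(traces)
    iu, ju = np.triu_indices(tensor.n_repeats, k=1)
    vals = corr[iu, ju]
    return {
        "mean_correlation": float(np.nanmean(vals)),
        "correlations": vals,
        "traces": traces,
    }
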