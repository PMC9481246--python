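"""Core drift statistics.

Representational similarity (RS) of repeat population vectors, the
representational drift index (RDI) and its single-pair analogue,
per-unit stimulus reliability, setpoint similarity, behavioural tuning
with bootstrap significance, the sign constancy index (SCI), and the
RS-versus-behaviour regressions.

All correlations are Pearson.  Statistics over windows with missing
values use pairwise-complete data and refuse to produce a value when
fewer than half of the points are present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import (
    DegenerateInputError,
    RepeatTensor,
    Session,
    MIN_COMPLETE_FRACTION,
    zscore,
)

__all__ = [
    "RSMatrix",
    "DriftSummary",
    "population_vectors",
    "rs_matrix",
    "drift_summary",
    "pairwise_rdi",
    "stimulus_reliability",
    "setpoint_similarity",
    "behavior_correlation",
    "bootstrap_z",
    "sign_constancy_index",
    "repeat_behavior_means",
    "rs_vs_pupil_regression",
    "stimulus_setpoint_comparison",
    "ols_fit",
]

logger = logging.getLogger(__name__)


@dataclass
class RSMatrix:
    """Symmetric repeat-by-repeat Pearson-correlation matrix.

    ``rho[i, j]`` is the RS between repeats i and j (NaN where a repeat
    failed the completeness floor or was constant); ``blocks`` labels
    each repeat's presentation block.
    """

    rho: np.ndarray
    blocks: np.ndarray

    @property
    def n_repeats(self) -> int:
        return self.rho.shape[0]

    def off_diagonal_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_repeats, k=1)


@dataclass
class DriftSummary:
    """Within/between-block mean RS and the drift index.

    ``rdi = (cc_within - cc_between) / (cc_within + cc_between)``.
    """

    cc_within: float
    cc_between: float
    rdi: float


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over pairwise-complete entries; NaN if floor not met."""
    valid = np.isfinite(x) & np.isfinite(y)
    if valid.mean() < MIN_COMPLETE_FRACTION or valid.sum() < 3:
        return np.nan
    xv, yv = x[valid], y[valid]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))


def population_vectors(
    tensor: RepeatTensor, use_zscore: bool = False
) -> np.ndarray:
    """Concatenated per-repeat population vectors.

    Returns an (R, N*M) array.  Concatenation is unit-major (all M
    frames of unit 0, then unit 1, ...).  With ``use_zscore`` each
    unit's activity is z-scored over all repeats and frames of the
    tensor before concatenation.
    """
    data = tensor.data
    if use_zscore:
        flat = data.transpose(1, 0, 2).reshape(tensor.n_units, -1)
        flat = zscore(flat, axis=1)
        data = flat.reshape(
            tensor.n_units, tensor.n_repeats, tensor.n_frames
        ).transpose(1, 0, 2)
    return data.reshape(tensor.n_repeats, tensor.n_units * tensor.n_frames)


def rs_matrix(
    vectors: np.ndarray, blocks: np.ndarray | None = None
) -> RSMatrix:
    """Pearson RS matrix over repeat population vectors.

    Entries use pairwise-complete coordinates; a repeat that is
    constant, or falls below the 50% completeness floor against a
    partner, gets NaN there (constant repeats are logged).
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need at least 2 repeat vectors")
    r = vectors.shape[0]
    if blocks is None:
        blocks = np.zeros(r, dtype=int)
    rho = np.ones((r, r))
    if not np.isfinite(vectors).all():
        for i in range(r):
            for j in range(i + 1, r):
                rho[i, j] = rho[j, i] = _pairwise_pearson(
                    vectors[i], vectors[j]
                )
    else:
        sd = vectors.std(axis=1)
        const = sd == 0
        if const.any():
            logger.warning("%d constant repeat vector(s)", int(const.sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(vectors)
        rho[const, :] = np.nan
        rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    return RSMatrix(rho=rho, blocks=np.asarray(blocks))


def drift_summary(rs: RSMatrix) -> DriftSummary:
    """Within/between-block mean RS and the RDI over exactly two blocks.

    ``cc_within`` pools all non-identical same-block pairs from both
    blocks with equal pair weighting; ``cc_between`` averages all
    cross-block pairs.
    """
    labels = np.unique(rs.blocks)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 blocks, got {len(labels)}")
    for b in labels:
        if (rs.blocks == b).sum() < 2:
            raise ValueError(f"block {b} has fewer than 2 repeats")
    iu, ju = rs.off_diagonal_pairs()
    same = rs.blocks[iu] == rs.blocks[ju]
    cc_ws = float(np.nanmean(rs.rho[iu[same], ju[same]]))
    cc_bs = float(np.nanmean(rs.rho[iu[~same], ju[~same]]))
    denom = cc_ws + cc_bs
    if denom == 0:
        raise DegenerateInputError("RDI undefined: cc_within + cc_between = 0")
    return DriftSummary(cc_within=cc_ws, cc_between=cc_bs,
                        rdi=(cc_ws - cc_bs) / denom)


def pairwise_rdi(rho: float | np.ndarray) -> float | np.ndarray:
    """Single-pair drift index ``(1 - rho) / (1 + rho)``.

    The two-repeat limit of the RDI, where the within-block similarity
    is 1 by definition.  Infinite at ``rho = -1``.
    """
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(rho == -1.0, np.inf, (1.0 - rho) / (1.0 + rho))
    return float(out) if out.ndim == 0 else out


def stimulus_reliability(tensor: RepeatTensor) -> pd.DataFrame:
    """Per-unit stimulus reliability and setpoint.

    Reliability of unit k is the mean Pearson correlation of its
    M-length frame-response vector over all unordered repeat pairs
    (equal to the ordered-pair mean by symmetry).  Repeats in which the
    unit is constant are skipped and counted; a unit constant in all
    repeats gets NaN.  The setpoint is the unit's mean activity over
    all repeats and frames.
    """
    if tensor.n_repeats < 2 or tensor.n_frames < 2:
        raise ValueError("need >=2 repeats and >=2 frames")
    data = tensor.data  # R x N x M
    centered = data - np.nanmean(data, axis=2, keepdims=True)
    sd = np.nanstd(data, axis=2)  # R x N
    rel = np.empty(tensor.n_units)
    n_skipped = np.zeros(tensor.n_units, dtype=int)
    iu, ju = np.triu_indices(tensor.n_repeats, k=1)
    finite = np.isfinite(data).all()
    for k in range(tensor.n_units):
        ok = sd[:, k] > 0
        n_skipped[k] = int((~ok).sum())
        if finite:
            c = centered[:, k, :]  # R x M
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = (
                    (c @ c.T) / tensor.n_frames / np.outer(sd[:, k], sd[:, k])
                )
            pair_ok = ok[iu] & ok[ju]
            vals = corr[iu[pair_ok], ju[pair_ok]]
        else:  # missing bins: pairwise-complete per repeat pair
            vals = np.array(
                [
                    _pairwise_pearson(data[i, k, :], data[j, k, :])
                    for i, j in zip(iu, ju)
                    if ok[i] and ok[j]
                ]
            )
        rel[k] = float(np.nanmean(vals)) if len(vals) else np.nan
    return pd.DataFrame(
        {
            "unit_id": tensor.unit_ids,
            "reliability": rel,
            "setpoint": np.nanmean(data, axis=(0, 2)),
            "n_constant_repeats": n_skipped,
        }
    )


def setpoint_similarity(
    tensor: RepeatTensor, frame: int | None = None
) -> RSMatrix:
    """RS matrix of per-repeat setpoint vectors.

    The setpoint vector of a repeat is each unit's mean activity over
    the repeat's M frames; ``frame`` selects a single-frame variant
    instead of the average.
    """
    if tensor.n_repeats < 2:
        raise ValueError("need >=2 repeats")
    if frame is None:
        vectors = np.nanmean(tensor.data, axis=2)
    else:
        vectors = tensor.data[:, :, frame]
    return rs_matrix(vectors, blocks=tensor.blocks)


def behavior_correlation(
    activity: np.ndarray, behavior: np.ndarray
) -> float:
    """Pearson correlation of a unit's binned activity with a behaviour trace.

    Requires >= 10 pairwise-complete bins; returns NaN (with a logged
    warning) when either series is constant.
    """
    activity = np.asarray(activity, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if activity.shape != behavior.shape:
        raise ValueError("series must be aligned")
    valid = np.isfinite(activity) & np.isfinite(behavior)
    if valid.sum() < 10:
        raise ValueError("need >= 10 pairwise-complete bins")
    a, b = activity[valid], behavior[valid]
    if a.std() == 0 or b.std() == 0:
        logger.warning("constant series in behaviour correlation")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def bootstrap_z(
    activity: np.ndarray,
    behavior: np.ndarray,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Bootstrap significance of a unit's behavioural correlation.

    The unit's time bins are randomly permuted ``n_shuffles`` times
    (default 100); ``z = (rho - mu_sh) / sigma_sh`` from the shuffle
    mean and SD.  ``|z| > 1.96`` flags two-sided significance.
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    activity = np.asarray(activity, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    valid = np.isfinite(activity) & np.isfinite(behavior)
    a, b = activity[valid], behavior[valid]
    rho = behavior_correlation(a, b)
    # vectorized permutation correlations
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    perms = np.array([rng.permutation(len(a)) for _ in range(n_shuffles)])
    shuffled = (ac[perms] @ bc) / denom
    mu_sh = float(shuffled.mean())
    sigma_sh = float(shuffled.std())
    if sigma_sh == 0:
        raise DegenerateInputError("zero shuffle SD: Z undefined")
    z = (rho - mu_sh) / sigma_sh
    return {
        "rho": rho,
        "z": float(z),
        "mu_shuffle": mu_sh,
        "sigma_shuffle": sigma_sh,
        "significant": bool(abs(z) > 1.96),
    }


def sign_constancy_index(
    rho_block1: np.ndarray, rho_block2: np.ndarray
) -> float:
    """Fraction of units whose behavioural-correlation sign agrees between blocks.

    Zero correlations count as positive (deterministic tie-break).
    Pairs with a missing value are dropped.
    """
    r1 = np.asarray(rho_block1, dtype=float)
    r2 = np.asarray(rho_block2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("paired arrays required")
    valid = np.isfinite(r1) & np.isfinite(r2)
    if not valid.any():
        raise ValueError("no paired non-missing correlations")
    s1 = np.where(r1[valid] >= 0, 1, -1)
    s2 = np.where(r2[valid] >= 0, 1, -1)
    return float(np.mean(s1 == s2))


def repeat_behavior_means(
    session: Session, tensor: RepeatTensor, column: str = "pupil_width",
    use_zscore: bool = True,
) -> np.ndarray:
    """Mean behaviour value per repeat of the tensor.

    The trace is z-scored over the whole session first (default), so
    repeat means are comparable across sessions.
    """
    trace = session.behavior[column].to_numpy(dtype=float)
    if use_zscore:
        trace = zscore(trace)
    if tensor.bins is None:
        raise ValueError("tensor carries no bin indices")
    return np.nanmean(trace[tensor.bins], axis=1)


def ols_fit(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Least-squares line fit with R^2 on finite pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if x.std() == 0:
        raise DegenerateInputError("degenerate abscissa")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": r2,
        "n": int(len(x)),
    }


def rs_vs_pupil_regression(
    rs: RSMatrix,
    pupil_means: np.ndarray,
    running_means: np.ndarray | None = None,
    running_percentile: float | None = None,
    block_averages_only: bool = False,
) -> dict:
    """OLS of repeat-pair RS on the absolute pupil change.

    For each unordered repeat pair the abscissa is |mean z-scored pupil
    of repeat i - repeat j|.  ``running_percentile`` keeps only pairs
    whose |running change| is at or above that percentile (e.g. 80);
    ``block_averages_only`` fits the within/between-block average
    points instead of individual pairs.
    """
    iu, ju = rs.off_diagonal_pairs()
    d_pupil = np.abs(pupil_means[iu] - pupil_means[ju])
    sims = rs.rho[iu, ju]
    kept = np.ones(len(iu), dtype=bool)
    if running_percentile is not None:
        if running_means is None:
            raise ValueError("running_means required for the percentile filter")
        d_run = np.abs(running_means[iu] - running_means[ju])
        cutoff = np.percentile(d_run, running_percentile)
        kept = d_run >= cutoff
    pairs = pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "delta_pupil": d_pupil,
            "rs": sims,
            "same_block": rs.blocks[iu] == rs.blocks[ju],
            "kept": kept,
        }
    )
    if block_averages_only:
        grouped = pairs[kept].groupby("same_block").agg(
            delta_pupil=("delta_pupil", "mean"), rs=("rs", "mean")
        )
        x = grouped["delta_pupil"].to_numpy()
        y = grouped["rs"].to_numpy()
        if len(x) < 2:
            raise ValueError("need both pair groups for block averages")
        slope = (y[1] - y[0]) / (x[1] - x[0])
        fit = {
            "slope": float(slope),
            "intercept": float(y[0] - slope * x[0]),
            "r2": 1.0,
            "n": 2,
        }
    else:
        fit = ols_fit(pairs.loc[kept, "delta_pupil"], pairs.loc[kept, "rs"])
    return {**fit, "pairs": pairs}


def stimulus_setpoint_comparison(
    session: Session,
    stimulus_a: str,
    stimulus_b: str,
    n_frames: int = 30,
    n_pairs: int = 100,
    seed: int = 0,
    n_curve_bins: int = 40,
) -> dict:
    """Cross-block setpoint similarity for two stimulus types.

    For each of ``n_pairs`` draws and each stimulus: pick ``n_frames``
    random 1-s frames from each block, average every unit's response
    over them, and correlate the block-1 vector with the block-2
    vector.  Reports mean and SD per stimulus plus the similarity
    versus running-change curve (ΔZ = mean running in the block-2 draw
    minus block-1 draw, z-scored trace), binned into ``n_curve_bins``.
    """
    rng = np.random.default_rng(seed)
    run_z = zscore(session.behavior["running_speed"].to_numpy(dtype=float))
    results: dict = {"per_stimulus": {}, "curve": {}}
    scatter_sim: list[np.ndarray] = []
    scatter_dz: list[np.ndarray] = []
    scatter_stim: list[np.ndarray] = []
    for stim in (stimulus_a, stimulus_b):
        ep = session.epochs[session.epochs["stimulus_name"] == stim]
        blocks = np.sort(ep["block"].unique())
        if len(blocks) < 2:
            raise ValueError(f"stimulus {stim!r} not present in 2 blocks")
        bins_by_block = [
            ep.loc[ep["block"] == b, "bin"].to_numpy() for b in blocks[:2]
        ]
        for b in bins_by_block:
            if len(b) < n_frames:
                raise ValueError(f"fewer than {n_frames} frames in a block")
        sims = np.empty(n_pairs)
        dzs = np.empty(n_pairs)
        for p in range(n_pairs):
            pick1 = rng.choice(bins_by_block[0], size=n_frames, replace=False)
            pick2 = rng.choice(bins_by_block[1], size=n_frames, replace=False)
            v1 = np.nanmean(session.counts[:, pick1], axis=1)
            v2 = np.nanmean(session.counts[:, pick2], axis=1)
            sims[p] = _pairwise_pearson(v1, v2)
            dzs[p] = np.nanmean(run_z[pick2]) - np.nanmean(run_z[pick1])
        results["per_stimulus"][stim] = {
            "mean": float(np.nanmean(sims)),
            "sd": float(np.nanstd(sims)),
        }
        scatter_sim.append(sims)
        scatter_dz.append(dzs)
        scatter_stim.append(np.full(n_pairs, stim, dtype=object))
    dz_all = np.concatenate(scatter_dz)
    sim_all = np.concatenate(scatter_sim)
    edges = np.linspace(dz_all.min(), dz_all.max(), n_curve_bins + 1)
    idx = np.clip(np.digitize(dz_all, edges) - 1, 0, n_curve_bins - 1)
    curve = np.full(n_curve_bins, np.nan)
    for k in range(n_curve_bins):
        m = idx == k
        if m.any():
            curve[k] = float(np.nanmean(sim_all[m]))
    results["curve"] = {
        "bin_centers": 0.5 * (edges[:-1] + edges[1:]),
        "bin_means": curve,
    }
    results["pairs"] = pd.DataFrame(
        {
            "stimulus": np.concatenate(scatter_stim),
            "delta_running": dz_all,
            "similarity": sim_all,
        }
    )
    return results
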