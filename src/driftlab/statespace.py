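"""Principal-component analysis of population activity.

PCA is run on the units x time matrix of binned activity (each 1-s bin
a sample, each unit a variable), per-unit mean-centred but not
variance-normalized by default, so that the leading components retain
the dependence of loadings on overall activity levels.  The module
also provides the loading/behaviour regressions: distance along PC1
versus pupil change, and loadings versus per-unit properties
(stimulus reliability, mean activity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ols_fit
from .session import DegenerateInputError, zscore

__all__ = ["PCAResult", "pca_population", "pc_distance_vs_behavior",
           "loading_vs_unit_property"]


@dataclass
class PCAResult:
    """Result of a population PCA.

    ``components`` is (n_pcs, N) orthonormal directions in unit space;
    ``scores`` is (n_pcs, T) per-bin projections; ``loadings`` mirrors
    components, with each PC normalized to its maximum-magnitude entry
    for display; ``explained_variance_ratio`` gives per-PC fractions.
    """

    components: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Units x time reconstruction from the retained components."""
        return (self.components.T @ self.scores) + self.mean[:, None]


def pca_population(
    activity: np.ndarray,
    n_pcs: int | None = None,
    use_zscore: bool = False,
) -> PCAResult:
    """PCA of an N-units x T-bins activity matrix.

    Each unit is mean-centred (optionally z-scored) across time; the
    principal directions live in unit space and the scores are length-T
    time courses.  The sign of each component is fixed so its
    largest-magnitude loading is positive.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 2 or min(activity.shape) < 2:
        raise ValueError("need an N x T matrix with N, T >= 2")
    if not np.isfinite(activity).all():
        raise ValueError("PCA requires complete data; drop or fill NaNs")
    if use_zscore:
        centered = zscore(activity, axis=1)
        mean = activity.mean(axis=1) * 0.0
    else:
        mean = activity.mean(axis=1)
        centered = activity - mean[:, None]
    if np.allclose(centered, 0):
        raise DegenerateInputError("all-constant activity")
    n, t = centered.shape
    k = min(n, t) if n_pcs is None else min(n_pcs, n, t)
    # SVD of the centered matrix: rows units, columns time
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive
    for i in range(u.shape[1]):
        j = np.argmax(np.abs(u[:, i]))
        if u[j, i] < 0:
            u[:, i] *= -1
            vt[i, :] *= -1
    var = s**2 / t  # population convention, matches per-unit variances
    total = centered.var(axis=1).sum()
    components = u[:, :k].T
    scores = (s[:k, None] * vt[:k, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        loadings = components / np.abs(components).max(axis=1, keepdims=True)
    return PCAResult(
        components=components,
        scores=scores,
        loadings=loadings,
        explained_variance=var[:k],
        explained_variance_ratio=var[:k] / total,
        mean=mean if not use_zscore else np.zeros(n),
    )


def pc_distance_vs_behavior(
    pc_scores: np.ndarray,
    pupil: np.ndarray,
    max_pairs: int | None = 200_000,
    time_control_fraction: float = 0.10,
    seed: int = 0,
) -> dict:
    """Regress |ΔPC1| on |Δpupil| over bin pairs.

    For every non-identical bin pair, the distance on the PC is
    |score_i - score_j| and the behavioural change is the absolute
    difference of the z-scored pupil trace.  A second fit restricts to
    pairs whose time difference is below ``time_control_fraction`` of
    the series span (the passage-of-time control).  For long series the
    pair set is subsampled to ``max_pairs`` (seeded).
    """
    pc_scores = np.asarray(pc_scores, dtype=float)
    pupil = np.asarray(pupil, dtype=float)
    if pc_scores.shape != pupil.shape or pc_scores.ndim != 1:
        raise ValueError("aligned 1-D series required")
    valid = np.isfinite(pc_scores) & np.isfinite(pupil)
    idx = np.flatnonzero(valid)
    pupil_z = zscore(pupil[idx])
    scores = pc_scores[idx]
    t = len(idx)
    iu, ju = np.triu_indices(t, k=1)
    if max_pairs is not None and len(iu) > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(iu), size=max_pairs, replace=False)
        iu, ju = iu[pick], ju[pick]
    d_pc = np.abs(scores[iu] - scores[ju])
    d_pupil = np.abs(pupil_z[iu] - pupil_z[ju])
    dt = np.abs(idx[iu] - idx[ju])
    fit_all = ols_fit(d_pupil, d_pc)
    threshold = time_control_fraction * (idx.max() - idx.min())
    near = dt <= threshold
    out = {"all": fit_all, "time_threshold": float(threshold),
           "n_near_pairs": int(near.sum())}
    if near.sum() >= 3 and np.std(d_pupil[near]) > 0:
        out["time_controlled"] = ols_fit(d_pupil[near], d_pc[near])
    return out


def loading_vs_unit_property(
    loadings: np.ndarray, prop: np.ndarray
) -> dict[str, float]:
    """OLS of per-unit PC loadings on a unit property.

    Used for loadings versus stimulus reliability (expected no
    relation under independent mixing) and versus mean activity
    (expected positive relation).  Sign-flip of the PC leaves R^2
    unchanged.
    """
    return ols_fit(np.asarray(prop, float), np.asarray(loadings, float))
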