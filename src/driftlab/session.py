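"""Recording-session data model and on-disk layout.

A session bundles binned spiking activity (units x 1-s bins), behaviour
traces (pupil width/centre, running speed), a stimulus-epoch table and
unit metadata.  The on-disk layout is a plain directory:

``units.csv``
    columns ``unit_id, region``; row order fixes the unit axis.
``counts.csv`` or ``counts.h5``
    units x bins matrix of counts per bin (real-valued; empty cell /
    NaN = invalid interval).  The HDF5 variant stores dataset
    ``counts``.
``behavior.csv``
    columns ``bin, pupil_width, pupil_x, pupil_y, running_speed``;
    empty cells are missing values.
``epochs.csv``
    columns ``stimulus_name, block, repeat, frame, bin`` mapping each
    1-s stimulus frame to its time bin.
``meta.json``
    free-form provenance record.

CSV files are UTF-8 with a header row and ``.`` decimal separator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Session",
    "RepeatTensor",
    "SessionFormatError",
    "ShapeMismatchError",
    "DuplicateEpochError",
    "EpochRangeError",
    "DegenerateInputError",
    "MissingDataError",
    "load_session",
    "save_session",
    "zscore",
    "slice_repeats",
    "rebin",
]

MIN_COMPLETE_FRACTION = 0.5  # hard floor on pairwise-complete data


class SessionFormatError(ValueError):
    """A session directory is missing a file or has malformed content."""


class ShapeMismatchError(SessionFormatError):
    """Component shapes disagree (counts vs units vs behaviour)."""


class DuplicateEpochError(SessionFormatError):
    """Duplicate (stimulus, block, repeat, frame) key in the epoch table."""


class EpochRangeError(SessionFormatError):
    """Epoch references a bin outside the session time axis."""


class DegenerateInputError(ValueError):
    """Constant or otherwise degenerate input to a statistic."""


class MissingDataError(ValueError):
    """Fewer valid values than the completeness floor allows."""


EPOCH_COLUMNS = ["stimulus_name", "block", "repeat", "frame", "bin"]
BEHAVIOR_COLUMNS = ["pupil_width", "pupil_x", "pupil_y", "running_speed"]


@dataclass
class Session:
    """A binned recording session with behaviour and stimulus annotations.

    ``units`` is a DataFrame with columns ``unit_id`` and ``region``;
    ``counts`` is a units x bins float array (NaN = invalid interval);
    ``behavior`` is a DataFrame indexed by bin with the behaviour
    columns; ``epochs`` maps stimulus frames to bins.
    """

    units: pd.DataFrame
    counts: np.ndarray
    behavior: pd.DataFrame
    epochs: pd.DataFrame
    bin_width: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> "Session":
        """Check cross-referential integrity; return self."""
        if self.units["unit_id"].duplicated().any():
            raise SessionFormatError("duplicate unit_id in units table")
        if self.units["region"].isna().any():
            raise SessionFormatError("missing region label")
        if len(self.units) != self.n_units:
            raise ShapeMismatchError(
                f"{len(self.units)} units in table vs {self.n_units} count rows"
            )
        if len(self.behavior) != self.n_bins:
            raise ShapeMismatchError(
                f"behaviour has {len(self.behavior)} bins vs counts {self.n_bins}"
            )
        valid = ~np.isnan(self.counts)
        if (self.counts[valid] < 0).any():
            raise SessionFormatError("negative counts")
        ep = self.epochs
        if ep.duplicated(subset=["stimulus_name", "block", "repeat", "frame"]).any():
            raise DuplicateEpochError("duplicate epoch key")
        if len(ep) and ((ep["bin"] < 0) | (ep["bin"] >= self.n_bins)).any():
            raise EpochRangeError("epoch bin index outside session time axis")
        return self

    def region_mask(self, regions: str | list[str] | None) -> np.ndarray:
        if regions is None:
            return np.ones(self.n_units, dtype=bool)
        if isinstance(regions, str):
            regions = [regions]
        mask = self.units["region"].isin(regions).to_numpy()
        if not mask.any():
            raise ValueError(f"no units in region(s) {regions}")
        return mask


@dataclass
class RepeatTensor:
    """Repeats x units x frames slice of activity for one stimulus.

    ``data[r, n, m]`` is the response of unit n to frame m on repeat r;
    ``blocks[r]`` labels the presentation block of repeat r, in
    presentation order.
    """

    data: np.ndarray
    blocks: np.ndarray
    unit_ids: np.ndarray
    stimulus_name: str
    bins: np.ndarray | None = None  # repeats x frames bin indices

    @property
    def n_repeats(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


def zscore(x: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Z-score ``(x - mean) / sd`` with population SD, ignoring NaNs.

    Missing entries stay missing.  Raises
    :class:`DegenerateInputError` on constant input and
    :class:`MissingDataError` with fewer than 2 valid values.
    """
    x = np.asarray(x, dtype=float)
    if axis is None:
        valid = np.isfinite(x)
        if valid.sum() < 2:
            raise MissingDataError("need at least 2 non-missing values")
        mu = np.nanmean(x)
        sd = np.nanstd(x)  # population SD (divisor n)
        if sd == 0:
            raise DegenerateInputError("constant input: sigma = 0")
        return (x - mu) / sd
    mu = np.nanmean(x, axis=axis, keepdims=True)
    sd = np.nanstd(x, axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError("constant input along axis: sigma = 0")
    return (x - mu) / sd


def slice_repeats(
    session: Session,
    stimulus_name: str,
    blocks: list[int] | None = None,
    regions: str | list[str] | None = None,
    use_zscore: bool = False,
) -> RepeatTensor:
    """Extract the repeats x units x frames tensor for one stimulus.

    Repeats from the requested blocks are stacked in presentation
    order; ``use_zscore`` z-scores each unit over the whole session
    before slicing.
    """
    ep = session.epochs
    ep = ep[ep["stimulus_name"] == stimulus_name]
    if blocks is not None:
        ep = ep[ep["block"].isin(blocks)]
    if ep.empty:
        raise ValueError(
            f"no epochs for stimulus {stimulus_name!r} in blocks {blocks}"
        )
    mask = session.region_mask(regions)
    counts = session.counts
    if use_zscore:
        counts = zscore(counts, axis=1)
    counts = counts[mask]

    frames = np.sort(ep["frame"].unique())
    n_frames = len(frames)
    if not np.array_equal(frames, np.arange(n_frames)):
        raise SessionFormatError("frame indices must be 0..M-1")
    reps = (
        ep.groupby(["block", "repeat"])["bin"]
        .min()
        .reset_index()
        .sort_values("bin")  # presentation order
    )
    data = np.empty((len(reps), counts.shape[0], n_frames))
    bins = np.empty((len(reps), n_frames), dtype=int)
    block_labels = np.empty(len(reps), dtype=int)
    for r, (_, row) in enumerate(reps.iterrows()):
        sel = ep[(ep["block"] == row["block"]) & (ep["repeat"] == row["repeat"])]
        sel = sel.sort_values("frame")
        if len(sel) != n_frames:
            raise SessionFormatError(
                f"repeat {row['repeat']} of block {row['block']} has "
                f"{len(sel)} frames, expected {n_frames}"
            )
        idx = sel["bin"].to_numpy()
        data[r] = counts[:, idx]
        bins[r] = idx
        block_labels[r] = row["block"]
    return RepeatTensor(
        data=data,
        blocks=block_labels,
        unit_ids=session.units.loc[mask, "unit_id"].to_numpy(),
        stimulus_name=stimulus_name,
        bins=bins,
    )


def rebin(tensor: RepeatTensor, factor: int = 2) -> RepeatTensor:
    """Aggregate frames into non-overlapping groups of ``factor`` bins.

    Used for the longer-time-bin (e.g. 2 s) variant of the similarity
    analysis; trailing frames that do not fill a group are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    m = tensor.n_frames // factor * factor
    data = tensor.data[:, :, :m].reshape(
        tensor.n_repeats, tensor.n_units, m // factor, factor
    ).sum(axis=3)
    return RepeatTensor(
        data=data,
        blocks=tensor.blocks.copy(),
        unit_ids=tensor.unit_ids.copy(),
        stimulus_name=tensor.stimulus_name,
    )


def save_session(
    session: Session,
    path: str | Path,
    overwrite: bool = False,
    counts_format: str = "csv",
) -> Path:
    """Write a session directory; refuses to overwrite unless asked."""
    session.validate()
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True")
    path.mkdir(parents=True, exist_ok=True)
    session.units.to_csv(path / "units.csv", index=False)
    if counts_format == "h5":
        with h5py.File(path / "counts.h5", "w") as f:
            f.create_dataset("counts", data=session.counts)
    elif counts_format == "csv":
        pd.DataFrame(session.counts).to_csv(
            path / "counts.csv", index=False, header=False
        )
    else:
        raise ValueError(f"unknown counts_format {counts_format!r}")
    beh = session.behavior.copy()
    beh.insert(0, "bin", np.arange(len(beh)))
    beh.to_csv(path / "behavior.csv", index=False)
    session.epochs.to_csv(path / "epochs.csv", index=False)
    meta = dict(session.meta)
    meta["bin_width"] = session.bin_width
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def load_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`save_session`."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"session directory {path} not found")
    for name in ("units.csv", "behavior.csv", "epochs.csv", "meta.json"):
        if not (path / name).exists():
            raise SessionFormatError(f"missing {name} in {path}")
    units = pd.read_csv(path / "units.csv")
    if (path / "counts.h5").exists():
        with h5py.File(path / "counts.h5", "r") as f:
            counts = np.asarray(f["counts"], dtype=float)
    elif (path / "counts.csv").exists():
        counts = pd.read_csv(path / "counts.csv", header=None).to_numpy(float)
    else:
        raise SessionFormatError(f"missing counts.csv/counts.h5 in {path}")
    beh = pd.read_csv(path / "behavior.csv")
    beh = beh.drop(columns=["bin"]).reindex(columns=BEHAVIOR_COLUMNS)
    epochs = pd.read_csv(path / "epochs.csv").reindex(columns=EPOCH_COLUMNS)
    meta = json.loads((path / "meta.json").read_text())
    bin_width = float(meta.pop("bin_width", 1.0))
    return Session(
        units=units,
        counts=counts,
        behavior=beh,
        epochs=epochs,
        bin_width=bin_width,
        meta=meta,
    ).validate()
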