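"""Core domain types and I/O for internal-attention fMRI sessions.

The unit of analysis is a masked voxel time series: one row per TR
(repetition time, the fMRI sampling interval), one column per in-mask
voxel. Task structure is carried separately as an ordered list of trials
(BIDS-style events), from which TR-level condition labels are derived.

Volumes are exchanged as NIfTI (via :mod:`nibabel`) and events as
tab-separated tables (via :mod:`pandas`); in memory everything is plain
NumPy so the downstream classifier and decoder stay format-agnostic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.signal

logger = logging.getLogger(__name__)

#: The five internal-attention conditions, in canonical order. "MW" is
#: induced mind wandering; "Self" is self-referential processing; Feet and
#: Sounds are the two control states.
CONDITIONS: tuple[str, ...] = ("Breath", "Feet", "MW", "Self", "Sounds")

#: The three meditation-relevant states decoded during the breath-focus period.
MEDITATION_STATES: tuple[str, ...] = ("Breath", "MW", "Self")

#: Marker for the brief auditory cue preceding each stimulus trial.
INSTRUCTION = "Instruction"

VALID_TRIAL_TYPES = frozenset(CONDITIONS) | {INSTRUCTION}

#: Stimulus trial durations used in the task, seconds (inclusive bounds).
TRIAL_DURATION_BOUNDS: tuple[float, float] = (16.0, 50.0)


class AlignmentError(ValueError):
    """Mask and BOLD volumes do not share a voxel grid."""


class EventsParseError(ValueError):
    """An events table row cannot be interpreted."""


@dataclass
class BrainMask:
    """Set of voxel coordinates retained for analysis, on a 3D grid."""

    shape: tuple[int, int, int]
    included: np.ndarray  # (V, 3) int voxel coordinates, C-ordered

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=int)
        if self.included.ndim != 2 or self.included.shape[1] != 3:
            raise ValueError("included must be a (V, 3) coordinate array")
        if len(self.included) == 0:
            raise ValueError("mask includes no voxels")
        if (self.included < 0).any() or (self.included >= np.asarray(self.shape)).any():
            raise ValueError("mask coordinates fall outside the grid shape")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "BrainMask":
        arr = np.asarray(arr)
        if arr.ndim != 3:
            raise ValueError("mask array must be 3D")
        coords = np.argwhere(arr > 0)  # argwhere is C-ordered -> stable voxel order
        return cls(shape=tuple(arr.shape), included=coords)

    def to_array(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.uint8)
        out[tuple(self.included.T)] = 1
        return out

    @property
    def n_voxels(self) -> int:
        return len(self.included)


@dataclass
class VoxelTimeSeries:
    """A (TR x voxel) signal matrix with its sampling interval and voxel order."""

    data: np.ndarray  # (T, V) float
    tr_seconds: float
    voxel_ids: np.ndarray  # (V, 3) voxel coordinates (stable ordering)
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must be a non-empty (T, V) matrix")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.voxel_ids) != self.data.shape[1]:
            raise ValueError("voxel_ids length must equal the voxel count")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_trs * self.tr_seconds


@dataclass
class TrialRecord:
    """One task trial: an attention condition held over a time interval."""

    condition: str
    onset_seconds: float
    duration_seconds: float
    block_index: int
    rating: Optional[int] = None  # 1-4 subjective attention rating, rated trials only

    def __post_init__(self) -> None:
        if self.condition not in VALID_TRIAL_TYPES:
            raise EventsParseError(
                f"unknown trial_type {self.condition!r}; expected one of "
                f"{sorted(VALID_TRIAL_TYPES)}"
            )
        if self.duration_seconds <= 0:
            raise ValueError("trial duration must be positive")
        if self.condition != INSTRUCTION:
            lo, hi = TRIAL_DURATION_BOUNDS
            if not lo <= self.duration_seconds <= hi:
                raise ValueError(
                    f"stimulus trial duration {self.duration_seconds} outside [{lo}, {hi}]"
                )
        if self.rating is not None:
            if self.condition == "MW":
                raise ValueError("MW trials are never rated")
            if not 1 <= int(self.rating) <= 4:
                raise ValueError("rating must be in 1..4")

    @property
    def end_seconds(self) -> float:
        return self.onset_seconds + self.duration_seconds


@dataclass
class IADesign:
    """The internal-attention task design: ordered trials over blocks.

    Per block, the summed stimulus seconds of every condition must equal
    ``per_condition_block_seconds`` (72 s in the reference task, giving
    432 labeled seconds per condition over 6 blocks).
    """

    trials: list[TrialRecord]
    n_blocks: int
    order_set_id: int
    tr_seconds: float = 1.0
    per_condition_block_seconds: float = 72.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.trials:
            raise ValueError("design has no trials")
        if not 1 <= self.order_set_id <= 4:
            raise ValueError("order_set_id must be in 1..4")
        blocks = sorted({t.block_index for t in self.trials})
        if blocks != list(range(1, self.n_blocks + 1)):
            raise ValueError(
                f"expected blocks 1..{self.n_blocks}, found {blocks}"
            )
        for b in blocks:
            bt = [t for t in self.trials if t.block_index == b]
            for prev, cur in zip(bt, bt[1:]):
                if cur.onset_seconds < prev.end_seconds - 1e-9:
                    raise ValueError(
                        f"overlapping or unordered trials in block {b} at "
                        f"{cur.onset_seconds}s"
                    )
            per_cond: dict[str, float] = {}
            for t in bt:
                if t.condition != INSTRUCTION:
                    per_cond[t.condition] = per_cond.get(t.condition, 0.0) + t.duration_seconds
            for cond, total in per_cond.items():
                if abs(total - self.per_condition_block_seconds) > 1e-6:
                    raise ValueError(
                        f"block {b} carries {total}s of {cond}, expected "
                        f"{self.per_condition_block_seconds}s"
                    )

    @property
    def stimulus_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.condition != INSTRUCTION]

    @property
    def end_seconds(self) -> float:
        return max(t.end_seconds for t in self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [t.onset_seconds for t in self.trials],
                "duration": [t.duration_seconds for t in self.trials],
                "trial_type": [t.condition for t in self.trials],
                "block": [t.block_index for t in self.trials],
                "rating": [t.rating if t.rating is not None else np.nan for t in self.trials],
            }
        )


@dataclass
class LabeledSamples:
    """TR-level feature rows paired with condition labels and block structure."""

    features: np.ndarray  # (N, V)
    labels: np.ndarray  # (N,) condition strings, Instruction excluded
    blocks: np.ndarray  # (N,) block index per sample
    trial_ids: np.ndarray  # (N,) index into the design's trial list

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.blocks = np.asarray(self.blocks, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        n = len(self.features)
        if not (len(self.labels) == len(self.blocks) == len(self.trial_ids) == n):
            raise ValueError("features, labels, blocks, trial_ids must share length")
        if INSTRUCTION in set(self.labels.tolist()):
            raise ValueError("labeled samples must exclude Instruction periods")

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def present_conditions(self) -> list[str]:
        present = set(self.labels.tolist())
        return [c for c in CONDITIONS if c in present]


# ---------------------------------------------------------------------------
# I/O


def save_session(
    ts: VoxelTimeSeries,
    mask: BrainMask,
    design: IADesign,
    bold_path: Path | str,
    mask_path: Path | str,
    events_path: Path | str,
) -> None:
    """Write a session as 4D NIfTI + 3D mask NIfTI + events TSV.

    Inverse of :func:`load_session` for data defined on ``mask``.
    """
    if ts.n_voxels != mask.n_voxels:
        raise AlignmentError("time series voxel count does not match mask")
    vol = np.zeros(mask.shape + (ts.n_trs,), dtype=np.float64)
    i, j, k = mask.included.T
    vol[i, j, k, :] = ts.data.T
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(bold_path))
    nib.save(nib.Nifti1Image(mask.to_array(), affine), str(mask_path))
    design.to_frame().to_csv(events_path, sep="\t", index=False, na_rep="n/a")


def load_session(
    bold_path: Path | str,
    mask_path: Path | str,
    events_path: Path | str,
    tr_seconds: Optional[float] = None,
    subject_id: str = "subject",
    per_condition_block_seconds: Optional[float] = None,
    order_set_id: int = 1,
) -> tuple[VoxelTimeSeries, IADesign]:
    """Load a 4D BOLD NIfTI, restrict it to a mask, and parse the events TSV.

    The voxel ordering is the C-order traversal of in-mask coordinates, so
    repeated loads of the same files give identical column orderings.
    ``tr_seconds`` defaults to the NIfTI header pixdim[4] when present.
    ``per_condition_block_seconds`` is inferred from the events when not
    given (the design invariant requires every condition's per-block total
    to equal it; 72 s in the reference task).
    """
    bold_img = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    bold = np.asarray(bold_img.dataobj, dtype=float)
    if bold.ndim != 4:
        raise ValueError(f"expected 4D BOLD, got shape {bold.shape}")
    mask_arr = np.asarray(mask_img.dataobj)
    if mask_arr.shape != bold.shape[:3]:
        raise AlignmentError(
            f"mask grid {mask_arr.shape} does not match BOLD grid {bold.shape[:3]}"
        )
    mask = BrainMask.from_array(mask_arr)
    i, j, k = mask.included.T
    data = bold[i, j, k, :].T  # (T, V)
    if tr_seconds is None:
        hdr_tr = float(bold_img.header.get_zooms()[3]) if len(bold_img.header.get_zooms()) > 3 else 0.0
        tr_seconds = hdr_tr if hdr_tr > 0 else 1.0
    ts = VoxelTimeSeries(
        data=data, tr_seconds=tr_seconds, voxel_ids=mask.included, subject_id=subject_id
    )

    events = pd.read_csv(events_path, sep="\t", na_values=["n/a"])
    required = {"onset", "duration", "trial_type"}
    missing = required - set(events.columns)
    if missing:
        raise EventsParseError(f"events table missing columns: {sorted(missing)}")
    trials: list[TrialRecord] = []
    for _, row in events.iterrows():
        rating = row.get("rating")
        rating = None if rating is None or pd.isna(rating) else int(rating)
        block = int(row["block"]) if "block" in events.columns and not pd.isna(row.get("block")) else 1
        trials.append(
            TrialRecord(
                condition=str(row["trial_type"]),
                onset_seconds=float(row["onset"]),
                duration_seconds=float(row["duration"]),
                block_index=block,
                rating=rating,
            )
        )
    scan_end = ts.duration_seconds
    for t in trials:
        if t.end_seconds > scan_end + 1e-6:
            raise ValueError(
                f"trial at {t.onset_seconds}s extends past the scan end ({scan_end}s)"
            )
    n_blocks = max(t.block_index for t in trials)
    if per_condition_block_seconds is None:
        totals: dict[tuple[int, str], float] = {}
        for t in trials:
            if t.condition != INSTRUCTION:
                key = (t.block_index, t.condition)
                totals[key] = totals.get(key, 0.0) + t.duration_seconds
        per_condition_block_seconds = max(totals.values())
    design = IADesign(
        trials=trials,
        n_blocks=n_blocks,
        order_set_id=order_set_id,
        tr_seconds=tr_seconds,
        per_condition_block_seconds=per_condition_block_seconds,
    )
    return ts, design


# ---------------------------------------------------------------------------
# Preprocessing and label extraction


def preprocess_timeseries(
    ts: VoxelTimeSeries, detrend: bool = True, zscore: bool = True
) -> VoxelTimeSeries:
    """Per-voxel linear detrending and/or standardization over time.

    Constant (zero-variance) voxels are set to all-zero and logged rather
    than dropped, so voxel indexing stays stable for importance maps.
    Standardization uses the sample SD (ddof=1), which makes the operation
    idempotent on already-standardized data.
    """
    data = ts.data.copy()
    if detrend:
        data = scipy.signal.detrend(data, axis=0, type="linear")
    if zscore:
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1) if data.shape[0] > 1 else np.zeros(data.shape[1])
        constant = sd <= 1e-12
        if constant.any():
            logger.warning(
                "%d constant voxel(s) zeroed during standardization (indices %s)",
                int(constant.sum()),
                np.flatnonzero(constant)[:10].tolist(),
            )
        safe_sd = np.where(constant, 1.0, sd)
        data = (data - mean) / safe_sd
        data[:, constant] = 0.0
    return replace(ts, data=data)


def extract_labeled_samples(
    ts: VoxelTimeSeries, design: IADesign, lag_trs: int = 0
) -> LabeledSamples:
    """Assign each TR to the stimulus trial active at its lag-shifted time.

    A TR starting at time ``t`` is attributed to the trial covering
    ``t - lag_trs * tr`` under the half-open rule ``onset <= time < onset +
    duration`` (the hemodynamic response trails the stimulus, so a positive
    lag pushes labels later in the scan). Instruction periods and TRs whose
    shifted time falls outside any stimulus trial yield no sample.
    """
    if lag_trs < 0:
        raise ValueError("lag_trs must be >= 0")
    tr = ts.tr_seconds
    stim = design.stimulus_trials
    trial_index = {id(t): i for i, t in enumerate(design.trials)}
    feats, labels, blocks, trial_ids = [], [], [], []
    for t_idx in range(ts.n_trs):
        shifted = t_idx * tr - lag_trs * tr
        for trial in stim:
            if trial.onset_seconds - 1e-9 <= shifted < trial.end_seconds - 1e-9:
                feats.append(ts.data[t_idx])
                labels.append(trial.condition)
                blocks.append(trial.block_index)
                trial_ids.append(trial_index[id(trial)])
                break
    if not feats:
        raise ValueError("no TR falls inside any stimulus trial after the lag shift")
    return LabeledSamples(
        features=np.asarray(feats),
        labels=np.asarray(labels),
        blocks=np.asarray(blocks),
        trial_ids=np.asarray(trial_ids),
    )
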