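"""Classifier importance maps and group frequency maps.

A voxel's importance for a condition is the product of its classifier
weight for that condition and the z-scored mean activation of the voxel
during the condition (z-scoring across voxels of the condition-mean
activation vector). Maps are thresholded at +/- k SD of the within-map
importance distribution to flag the voxels that drive correct
classification, carrying the sign of the underlying activation. Group
frequency maps count, per voxel, how many subjects' thresholded maps
include it — overall and split by activation sign.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import SubjectClassifier
from .core import LabeledSamples

logger = logging.getLogger(__name__)


@dataclass
class ImportanceMap:
    """Per-voxel importance of one condition for one subject."""

    condition: str
    values: np.ndarray  # (V,)
    activation_sign: np.ndarray  # (V,) in {-1, 0, +1}, sign of z-scored mean activation
    threshold_sd: Optional[float] = None
    flagged: Optional[np.ndarray] = None  # (V,) bool, set by threshold_importance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.activation_sign = np.asarray(self.activation_sign, dtype=int)
        if self.values.shape != self.activation_sign.shape:
            raise ValueError("values and activation_sign must share shape")
        if self.flagged is not None:
            self.flagged = np.asarray(self.flagged, dtype=bool)
            if self.flagged.shape != self.values.shape:
                raise ValueError("flagged must share the voxel grid")

    @property
    def n_voxels(self) -> int:
        return len(self.values)

    @property
    def flagged_positive(self) -> np.ndarray:
        if self.flagged is None:
            raise ValueError("map has not been thresholded")
        return self.flagged & (self.activation_sign > 0)

    @property
    def flagged_negative(self) -> np.ndarray:
        if self.flagged is None:
            raise ValueError("map has not been thresholded")
        return self.flagged & (self.activation_sign < 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel_id": np.arange(self.n_voxels),
                "importance": self.values,
                "activation_sign": self.activation_sign,
                "flagged": self.flagged if self.flagged is not None else False,
            }
        )


@dataclass
class FrequencyMap:
    """Per-voxel participant counts of flagged importance voxels."""

    condition: str
    counts_all: np.ndarray
    counts_positive: np.ndarray
    counts_negative: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        for name in ("counts_all", "counts_positive", "counts_negative"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        if not (
            len(self.counts_all)
            == len(self.counts_positive)
            == len(self.counts_negative)
        ):
            raise ValueError("count vectors must share the voxel grid")
        if (self.counts_all > self.n_subjects).any():
            raise ValueError("counts cannot exceed the number of subjects")
        if (
            self.counts_all < np.maximum(self.counts_positive, self.counts_negative)
        ).any():
            raise ValueError("overall counts cannot fall below either signed count")

    def histogram(self) -> dict[int, int]:
        """Number of voxels flagged by exactly k subjects, for k >= 1."""
        vals = self.counts_all[self.counts_all > 0]
        return {int(k): int((vals == k).sum()) for k in np.unique(vals)}


def compute_importance_map(
    classifier: SubjectClassifier,
    samples: LabeledSamples,
    condition: str,
    zscore_over: str = "voxels",
) -> ImportanceMap:
    """Importance = classifier weight x z-scored mean condition activation.

    ``zscore_over="voxels"`` (default) z-scores the condition-mean
    activation vector across voxels; ``"time"`` z-scores each voxel's time
    series over the condition's TRs first and then averages, an alternative
    reading kept behind this flag.
    """
    if condition not in samples.present_conditions:
        raise ValueError(f"condition {condition!r} absent from samples")
    if condition not in classifier.classes:
        raise ValueError(f"classifier has no weights for {condition!r}")
    rows = samples.features[samples.labels == condition]
    if zscore_over == "voxels":
        mean_act = rows.mean(axis=0)
        sd = mean_act.std()
        z = (mean_act - mean_act.mean()) / sd if sd > 0 else np.zeros_like(mean_act)
    elif zscore_over == "time":
        sd_t = rows.std(axis=0)
        safe = np.where(sd_t > 0, sd_t, 1.0)
        z = ((rows - rows.mean(axis=0)) / safe).mean(axis=0)
        z[sd_t == 0] = 0.0
    else:
        raise ValueError("zscore_over must be 'voxels' or 'time'")
    weights = classifier.weight_for(condition)
    return ImportanceMap(
        condition=condition,
        values=weights * z,
        activation_sign=np.sign(z).astype(int),
    )


def threshold_importance(
    imp: ImportanceMap, k_sd: float = 2.0, center: str = "mean"
) -> ImportanceMap:
    """Flag voxels whose importance deviates more than ``k_sd`` SDs.

    The deviation is measured from the map mean (``center="mean"``, the
    conventional reading of a +/- k SD threshold) or from zero
    (``center="zero"``); the SD is the population SD of the map's
    importance values. A zero-variance map flags nothing and logs a note.
    """
    if imp.n_voxels < 2:
        raise ValueError("thresholding needs at least 2 voxels")
    vals = imp.values
    mu = vals.mean() if center == "mean" else 0.0
    if center not in ("mean", "zero"):
        raise ValueError("center must be 'mean' or 'zero'")
    sd = vals.std()  # population SD
    if sd == 0:
        logger.warning(
            "importance map for %s has zero variance; nothing flagged", imp.condition
        )
        flagged = np.zeros(imp.n_voxels, dtype=bool)
    else:
        flagged = np.abs(vals - mu) > k_sd * sd
    return replace(imp, threshold_sd=k_sd, flagged=flagged)


def importance_frequency_map(maps: Sequence[ImportanceMap]) -> FrequencyMap:
    """Count, per voxel, how many subjects' thresholded maps flag it.

    All maps must share the voxel grid (one map per subject, same
    condition); for real data this presumes prior spatial normalization.
    """
    if not maps:
        raise ValueError("no maps supplied")
    n_vox = maps[0].n_voxels
    cond = maps[0].condition
    for m in maps:
        if m.n_voxels != n_vox:
            raise ValueError("maps do not share a voxel grid")
        if m.flagged is None:
            raise ValueError("all maps must be thresholded first")
        if m.condition != cond:
            raise ValueError("maps mix conditions")
    counts_all = np.sum([m.flagged for m in maps], axis=0)
    counts_pos = np.sum([m.flagged_positive for m in maps], axis=0)
    counts_neg = np.sum([m.flagged_negative for m in maps], axis=0)
    return FrequencyMap(
        condition=cond,
        counts_all=counts_all,
        counts_positive=counts_pos,
        counts_negative=counts_neg,
        n_subjects=len(maps),
    )
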