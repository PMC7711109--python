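"""TR-by-TR decoding of the meditation period and mental-event segmentation.

The subject's five-state classifier is applied to each meditation TR; its
probabilities are restricted to the three meditation-relevant states
(Breath, MW, Self), renormalized, and decided by argmax, producing a
continuous estimate of the focus of attention. Maximal runs of >= 3
consecutive identical decisions form "mental events".
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import SubjectClassifier
from .core import MEDITATION_STATES, VoxelTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class DecodedSession:
    """Per-TR state decisions and probabilities for one meditation period."""

    decisions: np.ndarray  # (T,) state strings
    probabilities: np.ndarray  # (T, len(state_set)), rows sum to 1
    state_set: tuple[str, ...]
    tr_seconds: float = 1.0
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.decisions = np.asarray(self.decisions)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.decisions) != len(self.probabilities):
            raise ValueError("decisions and probabilities must share length")
        if self.probabilities.shape[1] != len(self.state_set):
            raise ValueError("one probability column per state required")

    @property
    def n_trs(self) -> int:
        return len(self.decisions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"tr": np.arange(self.n_trs), "decision": self.decisions})
        for j, s in enumerate(self.state_set):
            df[f"p_{s}"] = self.probabilities[:, j]
        return df


@dataclass(frozen=True)
class MentalEvent:
    """A maximal run of >= min_len consecutive identical state decisions."""

    state: str
    onset_tr: int
    duration_trs: int

    def __post_init__(self) -> None:
        if self.duration_trs < 1:
            raise ValueError("event duration must be >= 1 TR")


def decode_meditation(
    classifier: SubjectClassifier,
    meditation_ts: VoxelTimeSeries,
    state_set: Sequence[str] = MEDITATION_STATES,
) -> DecodedSession:
    """Decode each meditation TR by restriction + renormalization.

    The full five-class probabilities are computed, the columns of
    ``state_set`` kept and renormalized, and the argmax taken. Exact ties
    are broken by the fixed state order (Breath < MW < Self) and logged.
    """
    state_set = tuple(state_set)
    missing = [s for s in state_set if s not in classifier.classes]
    if missing:
        raise ValueError(f"classifier lacks states {missing}")
    proba5 = classifier.predict_proba(meditation_ts.data)
    cols = [classifier.classes.index(s) for s in state_set]
    proba = proba5[:, cols]
    proba = proba / proba.sum(axis=1, keepdims=True)
    idx = proba.argmax(axis=1)
    ties = (proba == proba.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info(
            "%d TR(s) had tied probabilities; broken by state order %s",
            int(ties.sum()),
            state_set,
        )
    decisions = np.asarray([state_set[i] for i in idx])
    return DecodedSession(
        decisions=decisions,
        probabilities=proba,
        state_set=state_set,
        tr_seconds=meditation_ts.tr_seconds,
        subject_id=meditation_ts.subject_id,
    )


def segment_mental_events(
    decisions: Sequence[str], min_len: int = 3
) -> list[MentalEvent]:
    """Segment a decision sequence into mental events.

    A mental event is a maximal run of identical consecutive decisions of
    length >= ``min_len`` (default 3 TRs); shorter runs are left
    unassigned. With ``min_len=1`` the events partition the sequence.
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("empty decision sequence")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    events: list[MentalEvent] = []
    onset = 0
    for state, run in itertools.groupby(decisions):
        length = len(list(run))
        if length >= min_len:
            events.append(MentalEvent(state=state, onset_tr=onset, duration_trs=length))
        onset += length
    return events


def events_to_frame(events: Sequence[MentalEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "state": [e.state for e in events],
            "onset_tr": [e.onset_tr for e in events],
            "duration_trs": [e.duration_trs for e in events],
        }
    )
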