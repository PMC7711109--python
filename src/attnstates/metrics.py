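"""Individual attention metrics and the group-level statistics over them.

From one decoded meditation session: per state, the percentage of TRs
decided as the state, the number of mental events, and the mean and sample
SD of event durations (reported in seconds). Group inference is by
one-sample or paired two-sided t-tests with Cohen's d, and correlations
are pooled through the Fisher r-to-Z transform.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .decode import DecodedSession, MentalEvent
from .synth import MeditationTruth

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StateMetrics:
    percent_time: float
    n_events: int
    mean_duration_s: Optional[float]  # None when no events
    sd_duration_s: Optional[float]  # None when fewer than 2 events


@dataclass
class AttentionMetrics:
    """Per-state attention profile of one decoded meditation session."""

    subject_id: str
    per_state: dict[str, StateMetrics]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state, m in self.per_state.items():
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "state": state,
                    "percent_time": m.percent_time,
                    "n_events": m.n_events,
                    "mean_duration_s": m.mean_duration_s,
                    "sd_duration_s": m.sd_duration_s,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupStats:
    """Result of a one-sample or paired t-test over per-subject values."""

    name: str
    estimate: float
    t: float
    df: int
    p: float
    cohens_d: float
    n: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "cohens_d": self.cohens_d,
            "n": self.n,
        }


def compute_attention_metrics(
    decoded: DecodedSession,
    events: Sequence[MentalEvent],
    events_only: bool = False,
) -> AttentionMetrics:
    """Summarize a decoded session into per-state attention metrics.

    ``percent_time`` is 100 x (TRs decided as the state) / n_trs by
    default — every decoded TR counts, so the three values sum to 100.
    With ``events_only`` the numerator is restricted to TRs inside mental
    events (the stricter reading; values then sum to <= 100). Durations
    use the sample SD (ddof=1), undefined (None) below two events.
    """
    for e in events:
        seg = decoded.decisions[e.onset_tr : e.onset_tr + e.duration_trs]
        if len(seg) != e.duration_trs or not (seg == e.state).all():
            raise ValueError(
                f"event {e} does not match the decoded decision sequence"
            )
    n = decoded.n_trs
    out: dict[str, StateMetrics] = {}
    for state in decoded.state_set:
        if events_only:
            trs = sum(e.duration_trs for e in events if e.state == state)
        else:
            trs = int((decoded.decisions == state).sum())
        durations = np.array(
            [e.duration_trs * decoded.tr_seconds for e in events if e.state == state]
        )
        out[state] = StateMetrics(
            percent_time=100.0 * trs / n,
            n_events=len(durations),
            mean_duration_s=float(durations.mean()) if len(durations) else None,
            sd_duration_s=float(durations.std(ddof=1)) if len(durations) >= 2 else None,
        )
    return AttentionMetrics(subject_id=decoded.subject_id, per_state=out)


def _one_sample_t(values: np.ndarray, reference: float, name: str) -> GroupStats:
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{name}: zero variance in values; t-test undefined")
    t, p = scipy.stats.ttest_1samp(values, reference)
    mean = float(values.mean())
    return GroupStats(
        name=name,
        estimate=mean,
        t=float(t),
        df=n - 1,
        p=float(p),
        cohens_d=float((mean - reference) / sd),
        n=n,
    )


def group_accuracy_ttest(
    values: Sequence[float], reference: float, name: str = "one-sample t vs reference"
) -> GroupStats:
    """Two-sided one-sample t-test of per-subject values against a reference.

    Used for testing mean classification accuracy against the theoretical
    chance level. Cohen's d = (mean - reference) / sample SD.
    """
    return _one_sample_t(np.asarray(values, dtype=float), reference, name)


def fisher_z_group_test(
    correlations: Sequence[float], name: str = "Fisher-z correlation vs 0"
) -> GroupStats:
    """Group test of per-subject correlations via the Fisher r-to-Z transform.

    Each r is mapped through arctanh and the Z values are tested against 0
    with a one-sample two-sided t-test. Missing (NaN) correlations —
    subjects whose correlation was undefined — are excluded with a logged
    count; |r| = 1 is rejected (infinite Z).
    """
    r = np.asarray(correlations, dtype=float)
    n_missing = int(np.isnan(r).sum())
    if n_missing:
        logger.info("excluding %d undefined correlation(s) from the group test", n_missing)
        r = r[~np.isnan(r)]
    if (np.abs(r) >= 1.0).any():
        raise ValueError("|r| = 1 present; Fisher Z is infinite")
    z = np.arctanh(r)
    return _one_sample_t(z, 0.0, name)


def compare_breath_vs_other(
    metrics: Sequence[AttentionMetrics],
    other_state: str,
    metric: str = "percent_time",
) -> GroupStats:
    """Paired two-sided t-test of Breath vs another state across subjects.

    Tests whether participants attended longer to the breath than to
    ``other_state`` during meditation; Cohen's d is computed on the
    difference scores.
    """
    diffs = []
    for m in metrics:
        if "Breath" not in m.per_state or other_state not in m.per_state:
            raise ValueError(
                f"subject {m.subject_id} lacks paired Breath/{other_state} values"
            )
        diffs.append(
            getattr(m.per_state["Breath"], metric)
            - getattr(m.per_state[other_state], metric)
        )
    return _one_sample_t(
        np.asarray(diffs, dtype=float),
        0.0,
        name=f"paired t: Breath vs {other_state} ({metric})",
    )


def sequence_recovery_score(decoded: DecodedSession, truth: MeditationTruth) -> float:
    """Fraction of TRs whose decoded state equals the simulated hidden state.

    A synthetic-validation measure only; no ground truth exists for real
    meditation sessions.
    """
    if decoded.n_trs != truth.n_trs:
        raise ValueError("decoded session and truth differ in length")
    return float(np.mean(decoded.decisions == truth.state_sequence))


def cohort_metrics_frame(metrics: Sequence[AttentionMetrics]) -> pd.DataFrame:
    return pd.concat([m.to_frame() for m in metrics], ignore_index=True)
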