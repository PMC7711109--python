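"""Synthetic internal-attention sessions with known ground truth.

Each simulated subject carries five state-specific voxel patterns. The
labeled task period follows the block design of the reference task — six
blocks, 72 s of every condition per block, stimulus trials of 16-50 s each
preceded by a 2 s auditory instruction, condition order drawn from one of
four fixed order sets. The unlabeled meditation period is a first-order
Markov chain over the three meditation-relevant states (Breath, MW, Self)
whose per-TR hidden state is recorded as ground truth.

The signal model is deliberately minimal: a boxcar of the active state's
pattern plus i.i.d. Gaussian noise and an optional per-voxel linear drift.
There is no hemodynamic convolution by default, so TR labels are exact.
"""
from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    CONDITIONS,
    INSTRUCTION,
    MEDITATION_STATES,
    BrainMask,
    IADesign,
    TrialRecord,
    VoxelTimeSeries,
    save_session,
)

logger = logging.getLogger(__name__)

#: Four fixed condition orders standing in for the task's randomized order
#: sets (each condition appears once per set).
ORDER_SETS: dict[int, tuple[str, ...]] = {
    1: ("Breath", "Feet", "MW", "Self", "Sounds"),
    2: ("Sounds", "Breath", "Self", "Feet", "MW"),
    3: ("MW", "Self", "Breath", "Sounds", "Feet"),
    4: ("Feet", "Sounds", "MW", "Breath", "Self"),
}


class ConfigurationError(ValueError):
    """Generator parameters admit no valid design."""


@dataclass
class StatePatterns:
    """Mean voxel patterns for the five attention states of one subject."""

    patterns: np.ndarray  # (5, V)
    state_order: tuple[str, ...]
    overlap: float
    seed: int

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.shape[0] != len(self.state_order):
            raise ValueError("one pattern row per state required")
        if not np.isfinite(self.patterns).all():
            raise ValueError("patterns must be finite")

    def for_state(self, state: str) -> np.ndarray:
        return self.patterns[self.state_order.index(state)]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]


@dataclass
class MeditationTruth:
    """Ground-truth hidden-state sequence of a simulated meditation period."""

    state_sequence: np.ndarray  # (T,) state strings over MEDITATION_STATES
    transition_matrix: np.ndarray  # (3, 3) row-stochastic
    mean_dwell_trs: dict[str, float]

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        _check_stochastic(self.transition_matrix)

    @property
    def n_trs(self) -> int:
        return len(self.state_sequence)


def _check_stochastic(P: np.ndarray) -> None:
    if P.shape != (3, 3):
        raise ValueError("transition matrix must be 3x3 over (Breath, MW, Self)")
    if (P < -1e-12).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")


def make_state_patterns(
    n_voxels: int,
    overlap: float = 0.0,
    amplitude: float = 1.0,
    sparsity: float = 0.1,
    seed: int = 0,
) -> StatePatterns:
    """Draw five sparse voxel patterns with controllable pairwise overlap.

    Each state's pattern is ``sqrt(overlap) * shared + sqrt(1 - overlap) *
    unique`` where ``shared`` and the per-state ``unique`` components are
    independent sparse Gaussian vectors (about ``sparsity * n_voxels``
    nonzero entries of scale ``amplitude``). Expected pairwise pattern
    correlation therefore grows monotonically from ~0 at ``overlap=0`` to 1
    at ``overlap=1``, where all five rows coincide.
    """
    n_states = len(CONDITIONS)
    if n_voxels < n_states:
        raise ValueError(f"n_voxels must be >= {n_states}")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    def sparse_vec() -> np.ndarray:
        v = np.zeros(n_voxels)
        k = max(1, int(round(sparsity * n_voxels)))
        idx = rng.choice(n_voxels, size=k, replace=False)
        v[idx] = rng.normal(0.0, amplitude, size=k)
        return v

    shared = sparse_vec()
    rows = [
        np.sqrt(overlap) * shared + np.sqrt(1.0 - overlap) * sparse_vec()
        for _ in range(n_states)
    ]
    return StatePatterns(
        patterns=np.vstack(rows), state_order=CONDITIONS, overlap=overlap, seed=seed
    )


def _feasible_partitions(
    total: int, bounds: tuple[int, int], max_parts: int = 3
) -> list[tuple[int, ...]]:
    """Integer partitions of ``total`` into 1..max_parts parts within bounds."""
    lo, hi = bounds
    out: list[tuple[int, ...]] = []
    for k in range(1, max_parts + 1):
        for parts in itertools.combinations_with_replacement(range(lo, hi + 1), k):
            if sum(parts) == total:
                out.append(parts)
    return out


def build_ia_design(
    n_blocks: int = 6,
    per_condition_block_seconds: float = 72.0,
    trial_bounds: tuple[int, int] = (16, 50),
    order_set_id: int = 1,
    instruction_seconds: float = 2.0,
    tr_seconds: float = 1.0,
    seed: int = 0,
) -> IADesign:
    """Build a randomized block design honoring the per-condition time budget.

    Every (block, condition) pair receives trials whose durations lie in
    ``trial_bounds`` and sum exactly to ``per_condition_block_seconds``
    (a partition drawn uniformly from the feasible set). Within a block,
    trials are interleaved by cycling through the order set's condition
    sequence; each stimulus trial is preceded by an Instruction trial.
    """
    if order_set_id not in ORDER_SETS:
        raise ValueError("order_set_id must be in 1..4")
    budget = int(round(per_condition_block_seconds))
    if abs(budget - per_condition_block_seconds) > 1e-9:
        raise ConfigurationError("per_condition_block_seconds must be an integer")
    partitions = _feasible_partitions(budget, trial_bounds)
    if not partitions:
        raise ConfigurationError(
            f"no partition of {budget}s into 1-3 trials within {trial_bounds}"
        )
    rng = np.random.default_rng(seed)
    order = ORDER_SETS[order_set_id]

    trials: list[TrialRecord] = []
    clock = 0.0
    for block in range(1, n_blocks + 1):
        remaining: dict[str, list[int]] = {}
        for cond in order:
            parts = list(partitions[rng.integers(len(partitions))])
            rng.shuffle(parts)
            remaining[cond] = parts
        while any(remaining.values()):
            for cond in order:
                if not remaining[cond]:
                    continue
                dur = remaining[cond].pop(0)
                trials.append(
                    TrialRecord(INSTRUCTION, clock, instruction_seconds, block)
                )
                clock += instruction_seconds
                trials.append(TrialRecord(cond, clock, float(dur), block))
                clock += float(dur)
    return IADesign(
        trials=trials,
        n_blocks=n_blocks,
        order_set_id=order_set_id,
        tr_seconds=tr_seconds,
        per_condition_block_seconds=per_condition_block_seconds,
    )


def attach_ratings(
    design: IADesign,
    seed: int = 0,
    signal_coupling: float = 0.0,
    rated_fraction: float = 0.5,
    trial_quality: Optional[dict[int, float]] = None,
) -> IADesign:
    """Attach 1-4 subjective attention ratings to the later stimulus trials.

    Ratings cover the last ``rated_fraction`` of each condition's trials and
    are never attached to MW trials (participants were told to stop paying
    attention there). With ``signal_coupling`` > 0 and a per-trial quality
    map (e.g. trial-level signal amplitude), ratings correlate with quality;
    at 0 they are uniform noise, giving a null association.
    """
    rng = np.random.default_rng(seed)
    trials = [TrialRecord(t.condition, t.onset_seconds, t.duration_seconds, t.block_index) for t in design.trials]
    stim_idx = [i for i, t in enumerate(trials) if t.condition not in (INSTRUCTION, "MW")]
    n_rated = int(round(rated_fraction * len(stim_idx)))
    for i in stim_idx[len(stim_idx) - n_rated:]:
        quality = 0.0 if trial_quality is None else trial_quality.get(i, 0.0)
        latent = signal_coupling * quality + rng.normal()
        # map the latent score onto 1..4 by quartile-ish cuts
        rating = int(np.clip(np.digitize(latent, [-0.67, 0.0, 0.67]) + 1, 1, 4))
        trials[i] = TrialRecord(
            trials[i].condition,
            trials[i].onset_seconds,
            trials[i].duration_seconds,
            trials[i].block_index,
            rating=rating,
        )
    return IADesign(
        trials=trials,
        n_blocks=design.n_blocks,
        order_set_id=design.order_set_id,
        tr_seconds=design.tr_seconds,
        per_condition_block_seconds=design.per_condition_block_seconds,
    )


def simulate_ia_session(
    patterns: StatePatterns,
    design: IADesign,
    noise_sd: float = 1.0,
    drift_amplitude: float = 0.0,
    seed: int = 0,
    subject_id: str = "subject",
) -> tuple[VoxelTimeSeries, IADesign]:
    """Render a labeled task time series from state patterns and a design.

    Every TR inside a stimulus trial carries that condition's pattern;
    Instruction TRs carry baseline only. Gaussian noise of SD ``noise_sd``
    is added everywhere, plus an optional per-voxel linear drift whose
    endpoint magnitude is uniform in ``[-drift_amplitude, drift_amplitude]``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    tr = design.tr_seconds
    n_trs = int(np.ceil(design.end_seconds / tr))
    V = patterns.n_voxels
    data = np.zeros((n_trs, V))
    for trial in design.stimulus_trials:
        t0 = int(np.ceil(trial.onset_seconds / tr - 1e-9))
        t1 = int(np.ceil(trial.end_seconds / tr - 1e-9))
        data[t0:t1] += patterns.for_state(trial.condition)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    if drift_amplitude > 0:
        slope = rng.uniform(-drift_amplitude, drift_amplitude, size=V)
        ramp = np.linspace(0.0, 1.0, n_trs)[:, None]
        data += ramp * slope[None, :]
    mask = default_mask(V)
    ts = VoxelTimeSeries(
        data=data, tr_seconds=tr, voxel_ids=mask.included, subject_id=subject_id
    )
    return ts, design


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sticky_chain(pi: Sequence[float], stickiness: float = 0.8) -> np.ndarray:
    """Transition matrix ``s*I + (1-s) * 1 pi^T`` with stationary law ``pi``.

    Mean dwell of state i is ``1 / ((1 - s) * (1 - pi_i))`` TRs; with
    ``pi = (0.5, 0.3, 0.2)`` and ``s = 0.8`` the Breath dwell is 10 TRs.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (3,) or abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
        raise ValueError("pi must be a length-3 probability vector")
    if not 0.0 <= stickiness < 1.0:
        raise ValueError("stickiness must lie in [0, 1)")
    return stickiness * np.eye(3) + (1.0 - stickiness) * np.ones((3, 1)) @ pi[None, :]


def simulate_meditation_session(
    patterns: StatePatterns,
    transition_matrix: np.ndarray,
    duration_trs: int = 600,
    noise_sd: float = 1.0,
    seed: int = 0,
    tr_seconds: float = 1.0,
    initial_distribution: Optional[Sequence[float]] = None,
    subject_id: str = "subject",
) -> tuple[VoxelTimeSeries, MeditationTruth]:
    """Simulate the unlabeled breath-meditation period (default 600 TRs).

    The hidden state evolves as a first-order Markov chain over (Breath,
    MW, Self); every TR's row is the active state's pattern plus Gaussian
    noise. The initial state is drawn from ``initial_distribution``
    (stationary distribution by default).
    """
    P = np.asarray(transition_matrix, dtype=float)
    _check_stochastic(P)
    if duration_trs < 1:
        raise ValueError("duration_trs must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    init = (
        stationary_distribution(P)
        if initial_distribution is None
        else np.asarray(initial_distribution, dtype=float)
    )
    states = np.empty(duration_trs, dtype=object)
    s = rng.choice(3, p=init / init.sum())
    for t in range(duration_trs):
        states[t] = MEDITATION_STATES[s]
        s = rng.choice(3, p=P[s])
    V = patterns.n_voxels
    data = np.vstack([patterns.for_state(st) for st in states])
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=(duration_trs, V))
    mask = default_mask(V)
    ts = VoxelTimeSeries(
        data=data, tr_seconds=tr_seconds, voxel_ids=mask.included, subject_id=subject_id
    )
    dwell = {
        st: float(1.0 / (1.0 - P[i, i])) if P[i, i] < 1 else float("inf")
        for i, st in enumerate(MEDITATION_STATES)
    }
    truth = MeditationTruth(
        state_sequence=states, transition_matrix=P, mean_dwell_trs=dwell
    )
    return ts, truth


def default_mask(n_voxels: int) -> BrainMask:
    """A compact cuboid grid whose first ``n_voxels`` C-order voxels are in-mask."""
    nx = max(1, int(round(n_voxels ** (1.0 / 3.0))))
    ny = nx
    nz = int(np.ceil(n_voxels / (nx * ny)))
    arr = np.zeros(nx * ny * nz, dtype=np.uint8)
    arr[:n_voxels] = 1
    return BrainMask.from_array(arr.reshape(nx, ny, nz))


def write_synthetic_session(
    out_dir: Path | str,
    ts: VoxelTimeSeries,
    design: IADesign,
    truth: Optional[MeditationTruth] = None,
    params: Optional[dict] = None,
) -> dict[str, str]:
    """Write NIfTI + events TSV (+ truth sidecar TSV + manifest JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = default_mask(ts.n_voxels)
    paths = {
        "bold": str(out / "bold.nii.gz"),
        "mask": str(out / "mask.nii.gz"),
        "events": str(out / "events.tsv"),
    }
    save_session(ts, mask, design, paths["bold"], paths["mask"], paths["events"])
    if truth is not None:
        import pandas as pd

        paths["truth"] = str(out / "meditation_truth.tsv")
        pd.DataFrame(
            {"tr": np.arange(truth.n_trs), "state": truth.state_sequence}
        ).to_csv(paths["truth"], sep="\t", index=False)
    manifest = {"paths": paths, "params": params or {}}
    manifest_path = out / "generation_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(manifest_path)
    return paths
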