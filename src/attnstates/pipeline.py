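"""End-to-end synthetic-cohort pipeline and report writing.

Runs, per simulated subject: session generation -> block-wise
cross-validation of the five-state classifier -> importance maps ->
TR-by-TR decoding of the meditation period -> attention metrics; then the
group-level statistics. All randomness flows from one root seed through
`numpy.random.SeedSequence` spawning, so a fixed seed reproduces every
numeric output byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    AccuracyReport,
    ClassifierConfig,
    crossvalidate_by_block,
    train_state_classifier,
)
from .core import CONDITIONS, MEDITATION_STATES, extract_labeled_samples
from .decode import decode_meditation, events_to_frame, segment_mental_events
from .importance import (
    compute_importance_map,
    importance_frequency_map,
    threshold_importance,
)
from .metrics import (
    cohort_metrics_frame,
    compare_breath_vs_other,
    compute_attention_metrics,
    group_accuracy_ttest,
    sequence_recovery_score,
)
from .synth import (
    build_ia_design,
    make_state_patterns,
    simulate_ia_session,
    simulate_meditation_session,
    sticky_chain,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the synthetic-cohort pipeline, serialized verbatim
    into the run manifest."""

    n_subjects: int = 5
    n_voxels: int = 2000
    n_blocks: int = 6
    per_condition_block_seconds: float = 72.0
    trial_bounds: tuple[int, int] = (16, 50)
    instruction_seconds: float = 2.0
    tr_seconds: float = 1.0
    lag_trs: int = 0
    # signal model
    pattern_amplitude: float = 1.0
    pattern_sparsity: float = 0.1
    pattern_overlap: float = 0.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    # classifier
    penalty: float = 0.01
    chance_level: float = 0.20
    eligibility_alpha: float = 0.001
    # importance
    k_sd: float = 2.0
    # meditation period
    meditation_duration_trs: int = 600
    meditation_stationary: tuple[float, float, float] = (0.5, 0.3, 0.2)
    meditation_stickiness: float = 0.8
    min_event_len: int = 3
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.meditation_duration_trs < 1:
            raise ValueError("meditation_duration_trs must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        ClassifierConfig(penalty=self.penalty, chance_level=self.chance_level)

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(penalty=self.penalty, chance_level=self.chance_level)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trial_bounds"] = list(self.trial_bounds)
        d["meditation_stationary"] = list(self.meditation_stationary)
        return d

    @classmethod
    def from_file(cls, path: Path | str) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if "trial_bounds" in raw:
            raw["trial_bounds"] = tuple(raw["trial_bounds"])
        if "meditation_stationary" in raw:
            raw["meditation_stationary"] = tuple(raw["meditation_stationary"])
        return cls(**raw)


@dataclass
class SubjectResult:
    """All artifacts of one simulated subject's pass through the pipeline."""

    subject_id: str
    report: AccuracyReport
    metrics: "pd.DataFrame | None"
    recovery: float
    attention: object
    decoded: object
    events: list
    importance_maps: dict


def _subject_seeds(root_seed: int, n_subjects: int) -> list[dict[str, int]]:
    """Derive independent per-subject, per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(n_subjects)
    out = []
    for child in children:
        stage = child.generate_state(4, dtype=np.uint32)
        out.append(
            {
                "patterns": int(stage[0] % (2**31)),
                "design": int(stage[1] % (2**31)),
                "ia_noise": int(stage[2] % (2**31)),
                "meditation": int(stage[3] % (2**31)),
            }
        )
    return out


def run_subject(config: PipelineConfig, seeds: dict[str, int], subject_id: str) -> SubjectResult:
    """Run one subject end to end: simulate, validate, decode, summarize."""
    patterns = make_state_patterns(
        n_voxels=config.n_voxels,
        overlap=config.pattern_overlap,
        amplitude=config.pattern_amplitude,
        sparsity=config.pattern_sparsity,
        seed=seeds["patterns"],
    )
    design = build_ia_design(
        n_blocks=config.n_blocks,
        per_condition_block_seconds=config.per_condition_block_seconds,
        trial_bounds=config.trial_bounds,
        order_set_id=1 + seeds["design"] % 4,
        instruction_seconds=config.instruction_seconds,
        tr_seconds=config.tr_seconds,
        seed=seeds["design"],
    )
    ts, design = simulate_ia_session(
        patterns,
        design,
        noise_sd=config.noise_sd,
        drift_amplitude=config.drift_amplitude,
        seed=seeds["ia_noise"],
        subject_id=subject_id,
    )
    samples = extract_labeled_samples(ts, design, lag_trs=config.lag_trs)
    clf_config = config.classifier_config()
    report = crossvalidate_by_block(samples, clf_config, config.eligibility_alpha)
    classifier = train_state_classifier(samples, clf_config)

    imaps = {}
    for cond in CONDITIONS:
        imap = compute_importance_map(classifier, samples, cond)
        imaps[cond] = threshold_importance(imap, k_sd=config.k_sd)

    P = sticky_chain(config.meditation_stationary, config.meditation_stickiness)
    med_ts, truth = simulate_meditation_session(
        patterns,
        P,
        duration_trs=config.meditation_duration_trs,
        noise_sd=config.noise_sd,
        seed=seeds["meditation"],
        tr_seconds=config.tr_seconds,
        subject_id=subject_id,
    )
    decoded = decode_meditation(classifier, med_ts, MEDITATION_STATES)
    events = segment_mental_events(decoded.decisions, min_len=config.min_event_len)
    attention = compute_attention_metrics(decoded, events)
    recovery = sequence_recovery_score(decoded, truth)
    return SubjectResult(
        subject_id=subject_id,
        report=report,
        metrics=attention.to_frame(),
        recovery=recovery,
        attention=attention,
        decoded=decoded,
        events=events,
        importance_maps=imaps,
    )


def run_full_pipeline(
    config: PipelineConfig, out_dir: Path | str, force: bool = False
) -> Path:
    """Run the whole synthetic cohort and write all reports under ``out_dir``.

    Refuses to write into a non-empty directory unless ``force`` is set.
    Returns the run directory.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"{out} is not empty; pass force=True to overwrite its contents"
        )
    out.mkdir(parents=True, exist_ok=True)

    seeds = _subject_seeds(config.seed, config.n_subjects)
    results: list[SubjectResult] = []
    for i, subject_seeds in enumerate(seeds):
        subject_id = f"sub-{i + 1:02d}"
        logger.info("running %s", subject_id)
        results.append(run_subject(config, subject_seeds, subject_id))

    write_reports(out, config, seeds, results)
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_reports(
    out: Path,
    config: PipelineConfig,
    seeds: list[dict[str, int]],
    results: list[SubjectResult],
) -> None:
    """Write per-subject and group tables, then the run manifest."""
    out = Path(out)
    written: list[Path] = []

    for res in results:
        sub_dir = out / res.subject_id
        sub_dir.mkdir(parents=True, exist_ok=True)
        acc_path = sub_dir / "accuracy_report.json"
        acc_path.write_text(json.dumps(res.report.to_dict(), indent=2, sort_keys=True))
        conf_path = sub_dir / "confusion_matrix.csv"
        res.report.confusion.to_csv(conf_path)
        pred_path = sub_dir / "cv_predictions.tsv"
        pd.DataFrame(
            {
                "sample": np.arange(len(res.report.predictions)),
                "true": res.report.true_labels,
                "predicted": res.report.predictions,
            }
        ).to_csv(pred_path, sep="\t", index=False)
        timeline_path = sub_dir / "meditation_timeline.tsv"
        res.decoded.to_frame().to_csv(timeline_path, sep="\t", index=False)
        events_path = sub_dir / "mental_events.tsv"
        events_to_frame(res.events).to_csv(events_path, sep="\t", index=False)
        for cond, imap in res.importance_maps.items():
            ipath = sub_dir / f"importance_{cond}.tsv"
            imap.to_frame().to_csv(ipath, sep="\t", index=False)
            written.append(ipath)
        written += [acc_path, conf_path, pred_path, timeline_path, events_path]

    metrics_path = out / "attention_metrics.csv"
    cohort_metrics_frame([r.attention for r in results]).to_csv(
        metrics_path, index=False
    )
    written.append(metrics_path)

    for cond in CONDITIONS:
        freq = importance_frequency_map([r.importance_maps[cond] for r in results])
        fpath = out / f"frequency_map_{cond}.tsv"
        pd.DataFrame(
            {
                "voxel_id": np.arange(len(freq.counts_all)),
                "count_all": freq.counts_all,
                "count_positive": freq.counts_positive,
                "count_negative": freq.counts_negative,
            }
        ).to_csv(fpath, sep="\t", index=False)
        written.append(fpath)
        hpath = out / f"frequency_histogram_{cond}.csv"
        hist = freq.histogram()
        pd.DataFrame(
            {"n_subjects_sharing": list(hist.keys()), "n_voxels": list(hist.values())}
        ).to_csv(hpath, index=False)
        written.append(hpath)

    group: dict[str, object] = {
        "n_subjects": len(results),
        "n_eligible": int(sum(r.report.eligible for r in results)),
        "mean_recovery": float(np.mean([r.recovery for r in results])),
    }
    if len(results) >= 2:
        for cond in CONDITIONS:
            accs = [r.report.per_condition_accuracy[cond] for r in results]
            try:
                stats = group_accuracy_ttest(
                    accs, config.chance_level, name=f"accuracy vs chance: {cond}"
                )
                group[f"accuracy_vs_chance_{cond}"] = stats.to_dict()
            except ValueError as exc:  # zero variance (e.g. all at 100%)
                group[f"accuracy_vs_chance_{cond}"] = {
                    "name": f"accuracy vs chance: {cond}",
                    "estimate": float(np.mean(accs)),
                    "error": str(exc),
                }
        for other in ("MW", "Self"):
            try:
                stats = compare_breath_vs_other([r.attention for r in results], other)
                group[f"breath_vs_{other}_percent_time"] = stats.to_dict()
            except ValueError as exc:
                group[f"breath_vs_{other}_percent_time"] = {"error": str(exc)}
    group_path = out / "group_summary.json"
    group_path.write_text(json.dumps(group, indent=2, sort_keys=True))
    written.append(group_path)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "subject_seeds": seeds,
        "outputs": {
            str(p.relative_to(out)): _digest(p) for p in sorted(written)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
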