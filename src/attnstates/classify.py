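"""Per-subject multivariate classification of internal attention states.

The model is L2-penalized multinomial logistic regression over in-mask
voxels, fit per subject. Validation is leave-one-block-out: task blocks
are the exchangeable unit, so holding out whole blocks prevents temporal
leakage between neighbouring TRs of the same trial. Per-condition accuracy
is tested against the 1/K chance level (20% for five states) with a 1-df
chi-square goodness-of-fit test at the individual level.

Objective convention: the fit minimizes ``sum_i CE_i + penalty * ||W||_F^2``
where CE is the multinomial cross-entropy of sample i. The default
``penalty = 0.01`` maps onto scikit-learn's ``C = 1 / (2 * penalty)``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegression

from .core import CONDITIONS, MEDITATION_STATES, LabeledSamples, IADesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings of the state classifier.

    penalty : float
        Coefficient of the squared Frobenius norm of the weight matrix in
        the regularized objective (see module docstring). Default 0.01.
    chance_level : float
        Guessing accuracy, 1/K for K states (0.20 for the 5-state task).
    """

    penalty: float = 0.01
    chance_level: float = 0.20
    max_iter: int = 5000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if not 0.0 < self.chance_level < 1.0:
            raise ValueError("chance_level must lie in (0, 1)")

    @property
    def sklearn_C(self) -> float:
        return 1.0 / (2.0 * self.penalty)


@dataclass
class SubjectClassifier:
    """Trained per-subject weights: one row per state, one column per voxel."""

    weights: np.ndarray  # (K, V)
    intercepts: np.ndarray  # (K,)
    classes: tuple[str, ...]
    config: ClassifierConfig
    training_folds: str = "all data"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.weights.shape[0] != len(self.classes):
            raise ValueError("one weight row per class required")
        if self.intercepts.shape != (len(self.classes),):
            raise ValueError("one intercept per class required")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]

    def weight_for(self, condition: str) -> np.ndarray:
        return self.weights[self.classes.index(condition)]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_voxels:
            raise ValueError(
                f"input has {X.shape[1]} voxels, classifier expects {self.n_voxels}"
            )
        return X @ self.weights.T + self.intercepts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, rows summing to 1."""
        scores = self.decision_scores(X)
        scores -= scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        idx = proba.argmax(axis=1)
        return np.asarray([self.classes[i] for i in idx])


@dataclass
class AccuracyReport:
    """Cross-validated per-condition performance of one subject."""

    confusion: pd.DataFrame  # true (rows) x predicted (columns) counts
    per_condition_accuracy: dict[str, float]
    per_condition_chisq: dict[str, float]
    per_condition_p: dict[str, float]
    n_per_condition: dict[str, int]
    chance_level: float
    eligible: bool
    predictions: Optional[np.ndarray] = None  # per-sample, in sample order
    trial_ids: Optional[np.ndarray] = None
    true_labels: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "chance_level": self.chance_level,
            "eligible": bool(self.eligible),
            "per_condition_accuracy": self.per_condition_accuracy,
            "per_condition_chisq": self.per_condition_chisq,
            "per_condition_p": self.per_condition_p,
            "n_per_condition": self.n_per_condition,
            "confusion": {
                t: {p: int(self.confusion.loc[t, p]) for p in self.confusion.columns}
                for t in self.confusion.index
            },
        }


def train_state_classifier(
    samples: LabeledSamples, config: ClassifierConfig = ClassifierConfig()
) -> SubjectClassifier:
    """Fit the L2 multinomial logistic model on labeled TR samples.

    The objective is convex and the optimizer tolerance tight, so the fit
    is deterministic given data and config (up to floating-point roundoff
    in sum reductions).
    """
    labels = samples.labels
    present = sorted(set(labels.tolist()))
    if len(present) < 2:
        raise ValueError("at least two distinct condition labels are required")
    est = LogisticRegression(
        C=config.sklearn_C,
        solver="lbfgs",
        max_iter=config.max_iter,
        tol=config.tol,
    )
    est.fit(samples.features, labels)
    order = [c for c in CONDITIONS if c in est.classes_]
    reorder = [list(est.classes_).index(c) for c in order]
    return SubjectClassifier(
        weights=est.coef_[reorder],
        intercepts=est.intercept_[reorder],
        classes=tuple(order),
        config=config,
    )


def accuracy_vs_chance_chisq(
    n_correct: int, n_total: int, chance: float = 0.20
) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit of (correct, incorrect) vs chance.

    No continuity correction is applied; at the task's n = 432 per
    condition the correction is immaterial.
    """
    if not 0.0 < chance < 1.0:
        raise ValueError("chance must lie in (0, 1)")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    observed = np.array([n_correct, n_total - n_correct], dtype=float)
    expected = np.array([chance, 1.0 - chance]) * n_total
    stat, p = scipy.stats.chisquare(observed, expected)
    return float(stat), float(p)


def crossvalidate_by_block(
    samples: LabeledSamples,
    config: ClassifierConfig = ClassifierConfig(),
    eligibility_alpha: float = 0.001,
) -> AccuracyReport:
    """Leave-one-block-out cross-validation of the state classifier.

    Each task block serves once as the held-out fold; every sample is
    predicted exactly once while held out, and decisions are pooled over
    folds before computing per-condition accuracy, the confusion matrix,
    and the chi-square test against chance.
    """
    blocks = np.unique(samples.blocks)
    if len(blocks) < 2:
        raise ValueError(
            "block-wise cross-validation needs >= 2 blocks; supply a design "
            "with at least two blocks"
        )
    n = samples.n_samples
    predictions = np.empty(n, dtype=object)
    for b in blocks:
        held = samples.blocks == b
        train = LabeledSamples(
            features=samples.features[~held],
            labels=samples.labels[~held],
            blocks=samples.blocks[~held],
            trial_ids=samples.trial_ids[~held],
        )
        clf = train_state_classifier(train, config)
        predictions[held] = clf.predict(samples.features[held])
    assert not any(p is None for p in predictions)

    conds = samples.present_conditions
    confusion = pd.DataFrame(0, index=conds, columns=conds, dtype=int)
    for t, p in zip(samples.labels, predictions):
        confusion.loc[t, p] += 1
    accuracy, chisqs, pvals, counts = {}, {}, {}, {}
    for c in conds:
        row_n = int(confusion.loc[c].sum())
        correct = int(confusion.loc[c, c])
        accuracy[c] = correct / row_n
        stat, p = accuracy_vs_chance_chisq(correct, row_n, config.chance_level)
        chisqs[c], pvals[c] = stat, p
        counts[c] = row_n
    report = AccuracyReport(
        confusion=confusion,
        per_condition_accuracy=accuracy,
        per_condition_chisq=chisqs,
        per_condition_p=pvals,
        n_per_condition=counts,
        chance_level=config.chance_level,
        eligible=False,
        predictions=np.asarray(predictions),
        trial_ids=samples.trial_ids.copy(),
        true_labels=samples.labels.copy(),
    )
    if all(s in conds for s in MEDITATION_STATES):
        report.eligible = eligibility_check(report, alpha=eligibility_alpha)
    return report


def eligibility_check(
    report: AccuracyReport, alpha: float = 0.001, required: int = 2
) -> bool:
    """Decide whether a subject's classifier supports meditation decoding.

    True iff at least ``required`` (default 2) of the three meditation-
    relevant conditions (Breath, MW, Self) are classified above chance with
    chi-square p below ``alpha``.
    """
    missing = [s for s in MEDITATION_STATES if s not in report.per_condition_accuracy]
    if missing:
        raise ValueError(f"report lacks meditation-relevant conditions: {missing}")
    n_pass = sum(
        report.per_condition_accuracy[s] > report.chance_level
        and report.per_condition_p[s] < alpha
        for s in MEDITATION_STATES
    )
    return n_pass >= required


def trial_level_accuracy(report: AccuracyReport, design: IADesign) -> pd.DataFrame:
    """Per-trial fraction of correct TR decisions, joined with trial ratings.

    The finest faithful trial-level aggregate of cross-validated decisions:
    for each stimulus trial, the share of its TRs decoded as the trial's
    condition. MW trials (never rated) keep a missing rating.
    """
    if report.predictions is None or report.trial_ids is None:
        raise ValueError("report carries no per-sample predictions")
    correct = report.predictions == report.true_labels
    df = pd.DataFrame(
        {"trial_id": report.trial_ids, "correct": correct.astype(float)}
    )
    per_trial = df.groupby("trial_id")["correct"].mean().rename("accuracy")
    out = per_trial.reset_index()
    out["condition"] = [design.trials[i].condition for i in out["trial_id"]]
    out["rating"] = [
        np.nan if design.trials[i].rating is None else design.trials[i].rating
        for i in out["trial_id"]
    ]
    return out


def rating_accuracy_association(
    trial_accuracy: np.ndarray, ratings: np.ndarray
) -> tuple[float, int]:
    """Within-subject Pearson correlation of trial accuracy with ratings.

    Pairs with a missing rating are dropped. Returns ``(nan, n)`` with a
    logged explanation when either series is constant (the correlation is
    undefined there), rather than raising.
    """
    trial_accuracy = np.asarray(trial_accuracy, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    if len(trial_accuracy) != len(ratings):
        raise ValueError("trial_accuracy and ratings must have equal length")
    keep = ~np.isnan(ratings) & ~np.isnan(trial_accuracy)
    x, y = trial_accuracy[keep], ratings[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 rated trials")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning(
            "rating-accuracy correlation undefined: zero variance in %s",
            "ratings" if np.ptp(y) == 0 else "accuracy",
        )
        return float("nan"), n
    r, _ = scipy.stats.pearsonr(x, y)
    return float(r), n
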