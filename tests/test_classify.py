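"""Classifier training, block-wise cross-validation, chance tests, ratings."""
import logging

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import attnstates as a
from attnstates.classify import ClassifierConfig
from attnstates.core import CONDITIONS, LabeledSamples


def _orthogonal_samples(n_per_state=10, n_voxels=25, noise=0.0, seed=0, n_blocks=2):
    """Noiseless (or noisy) samples from 5 orthogonal one-hot-block patterns."""
    rng = np.random.default_rng(seed)
    feats, labels, blocks, trial_ids = [], [], [], []
    tid = 0
    for b in range(1, n_blocks + 1):
        for ci, cond in enumerate(CONDITIONS):
            pattern = np.zeros(n_voxels)
            pattern[ci * 5 : ci * 5 + 5] = 1.0
            for _ in range(n_per_state):
                feats.append(pattern + rng.normal(0, noise, n_voxels))
                labels.append(cond)
                blocks.append(b)
            trial_ids.extend([tid] * n_per_state)
            tid += 1
    return LabeledSamples(
        features=np.asarray(feats),
        labels=np.asarray(labels),
        blocks=np.asarray(blocks),
        trial_ids=np.asarray(trial_ids),
    )


# ---------------------------------------------------------------------------
# training


def test_noiseless_orthogonal_patterns_train_to_100():
    samples = _orthogonal_samples()
    clf = a.train_state_classifier(samples)
    assert (clf.predict(samples.features) == samples.labels).mean() == 1.0


def test_probabilities_sum_to_one():
    samples = _orthogonal_samples(noise=0.5, seed=1)
    clf = a.train_state_classifier(samples)
    proba = clf.predict_proba(np.random.default_rng(2).normal(size=(7, 25)))
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


def test_single_label_input_rejected():
    samples = _orthogonal_samples()
    only = samples.labels == "Breath"
    bad = LabeledSamples(
        features=samples.features[only],
        labels=samples.labels[only],
        blocks=samples.blocks[only],
        trial_ids=samples.trial_ids[only],
    )
    with pytest.raises(ValueError, match="two distinct"):
        a.train_state_classifier(bad)


def test_training_invariant_to_sample_order():
    samples = _orthogonal_samples(noise=1.0, seed=3)
    clf1 = a.train_state_classifier(samples)
    rng = np.random.default_rng(4)
    perm = rng.permutation(samples.n_samples)
    shuffled = LabeledSamples(
        features=samples.features[perm],
        labels=samples.labels[perm],
        blocks=samples.blocks[perm],
        trial_ids=samples.trial_ids[perm],
    )
    clf2 = a.train_state_classifier(shuffled)
    probe = np.random.default_rng(5).normal(size=(20, 25))
    np.testing.assert_allclose(
        clf1.predict_proba(probe), clf2.predict_proba(probe), atol=1e-8
    )


def test_penalty_maps_to_sklearn_C():
    assert ClassifierConfig(penalty=0.01).sklearn_C == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# chi-square vs chance


def test_chisq_hand_computed_values():
    # 216/432 vs 20%: (216-86.4)^2/86.4 + (216-345.6)^2/345.6 = 243.0
    stat, p = a.accuracy_vs_chance_chisq(216, 432, 0.2)
    assert stat == pytest.approx(243.0, abs=1e-9)
    assert p < 1e-15
    # near-expected counts give a tiny statistic
    stat, p = a.accuracy_vs_chance_chisq(86, 432, 0.2)
    assert stat == pytest.approx(0.00231481, abs=1e-6)
    assert p == pytest.approx(0.9616, abs=1e-3)


def test_chisq_input_validation():
    with pytest.raises(ValueError):
        a.accuracy_vs_chance_chisq(0, 0, 0.2)
    with pytest.raises(ValueError):
        a.accuracy_vs_chance_chisq(5, 4, 0.2)
    with pytest.raises(ValueError):
        a.accuracy_vs_chance_chisq(1, 4, 1.5)


def test_chisq_type_one_error_calibration():
    """Over 1000 chance-level subjects, alpha=0.05 rejections land in [0.03, 0.07]."""
    rng = np.random.default_rng(12)
    n, chance = 432, 0.2
    rejections = 0
    for _ in range(1000):
        correct = rng.binomial(n, chance)
        _, p = a.accuracy_vs_chance_chisq(correct, n, chance)
        rejections += p < 0.05
    assert 0.03 <= rejections / 1000 <= 0.07


# ---------------------------------------------------------------------------
# cross-validation


def test_cv_requires_two_blocks():
    samples = _orthogonal_samples(n_blocks=1)
    with pytest.raises(ValueError, match=">= 2 blocks"):
        a.crossvalidate_by_block(samples)


def test_cv_noiseless_session_is_perfect(noiseless_report):
    assert noiseless_report.per_condition_accuracy == {c: 1.0 for c in CONDITIONS}
    assert noiseless_report.eligible


def test_cv_confusion_rows_sum_to_432(noiseless_report):
    sums = noiseless_report.confusion.sum(axis=1)
    assert (sums == 432).all()


def test_cv_predictions_partition_samples(noiseless_report):
    assert len(noiseless_report.predictions) == 2160
    assert set(noiseless_report.predictions) <= set(CONDITIONS)


def test_cv_null_session_at_chance(null_report):
    """Pure-noise accuracy inside the 99% binomial band around 20%."""
    half_width = scipy.stats.norm.ppf(0.995) * np.sqrt(0.2 * 0.8 / 2160)
    mean_acc = np.mean(list(null_report.per_condition_accuracy.values()))
    assert abs(mean_acc - 0.2) < half_width


def test_accuracy_non_increasing_in_noise():
    """Matched-seed noise ladder: mean CV accuracy never rises with noise."""
    patterns = a.make_state_patterns(300, amplitude=0.2, sparsity=0.1, seed=31)
    design = a.build_ia_design(n_blocks=2, seed=31)
    means = []
    for noise_sd in (0.0, 1.0, 4.0, 16.0):
        ts, _ = a.simulate_ia_session(patterns, design, noise_sd=noise_sd, seed=32)
        samples = a.extract_labeled_samples(ts, design)
        rep = a.crossvalidate_by_block(samples)
        means.append(np.mean(list(rep.per_condition_accuracy.values())))
    assert all(x >= y - 1e-12 for x, y in zip(means, means[1:]))
    assert means[0] == 1.0 and means[-1] < 0.5


# ---------------------------------------------------------------------------
# eligibility


def _report(ps, accs):
    conds = list(a.MEDITATION_STATES)
    conf = pd.DataFrame(np.eye(3, dtype=int), index=conds, columns=conds)
    return a.AccuracyReport(
        confusion=conf,
        per_condition_accuracy=dict(zip(conds, accs)),
        per_condition_chisq={c: 0.0 for c in conds},
        per_condition_p=dict(zip(conds, ps)),
        n_per_condition={c: 432 for c in conds},
        chance_level=0.2,
        eligible=False,
    )


@pytest.mark.parametrize(
    "ps, accs, expected",
    [
        ([1e-5, 0.5, 1e-4], [0.5, 0.2, 0.5], True),  # 2 of 3 pass
        ([1e-5, 0.5, 0.5], [0.5, 0.2, 0.2], False),  # only 1 of 3
        ([1e-6, 1e-6, 1e-6], [0.5, 0.5, 0.5], True),  # 3 of 3
        ([1e-6, 1e-6, 1e-6], [0.1, 0.1, 0.5], False),  # significant but below chance
    ],
)
def test_eligibility_rule(ps, accs, expected):
    assert a.eligibility_check(_report(ps, accs)) is expected


def test_eligibility_missing_condition_errors():
    rep = _report([1e-5, 0.5, 1e-4], [0.5, 0.2, 0.5])
    del rep.per_condition_accuracy["Self"]
    with pytest.raises(ValueError, match="Self"):
        a.eligibility_check(rep)


# ---------------------------------------------------------------------------
# rating-accuracy association


def test_rating_accuracy_pearson_value():
    r, n = a.rating_accuracy_association([0.2, 0.5, 0.8, 1.0], [1, 2, 3, 4])
    assert n == 4
    assert r == pytest.approx(0.99591, abs=1e-4)


def test_rating_accuracy_constant_ratings_returns_nan(caplog):
    with caplog.at_level(logging.WARNING, logger="attnstates.classify"):
        r, n = a.rating_accuracy_association([0.2, 0.5, 0.8, 1.0], [3, 3, 3, 3])
    assert np.isnan(r) and n == 4
    assert any("zero variance" in rec.message for rec in caplog.records)


def test_rating_accuracy_perfect_linear_rescale():
    ratings = np.array([1, 2, 3, 4])
    acc = 0.1 + 0.2 * ratings
    r, _ = a.rating_accuracy_association(acc, ratings)
    assert r == pytest.approx(1.0)


def test_rating_accuracy_length_mismatch():
    with pytest.raises(ValueError):
        a.rating_accuracy_association([0.5, 0.5], [1, 2, 3])


def test_trial_level_accuracy_joins_ratings(noiseless_report, default_design):
    from attnstates.synth import attach_ratings

    rated = attach_ratings(default_design, seed=2)
    df = a.trial_level_accuracy(noiseless_report, rated)
    assert (df["accuracy"] == 1.0).all()  # noiseless decoding is perfect
    assert df.loc[df["condition"] == "MW", "rating"].isna().all()
    assert df["rating"].notna().sum() > 0
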