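"""Attention metrics and the group-level statistics over them."""
import numpy as np
import pytest

import attnstates as a
from attnstates.decode import DecodedSession, MentalEvent
from attnstates.metrics import StateMetrics
from attnstates.synth import MeditationTruth, sticky_chain


def _decoded(decisions, tr_seconds=1.0):
    decisions = np.asarray(decisions)
    states = a.MEDITATION_STATES
    proba = np.full((len(decisions), 3), 0.1)
    for i, d in enumerate(decisions):
        proba[i, states.index(d)] = 0.8
    return DecodedSession(
        decisions=decisions, probabilities=proba, state_set=states, tr_seconds=tr_seconds
    )


def test_percent_time_arithmetic():
    decisions = ["Breath"] * 300 + ["MW"] * 200 + ["Self"] * 100
    decoded = _decoded(decisions)
    events = a.segment_mental_events(decoded.decisions)
    m = a.compute_attention_metrics(decoded, events)
    assert m.per_state["Breath"].percent_time == pytest.approx(50.0)
    assert m.per_state["MW"].percent_time == pytest.approx(100 * 200 / 600)
    assert m.per_state["Self"].percent_time == pytest.approx(100 * 100 / 600)
    total = sum(s.percent_time for s in m.per_state.values())
    assert total == pytest.approx(100.0, abs=1e-9)


def test_event_duration_statistics_hand_computed():
    # Breath events of 3 and 4 TRs -> mean 3.5 s, sample SD 0.7071 s
    decisions = ["Breath"] * 3 + ["MW", "Self"] + ["Breath"] * 4 + ["MW"] * 3
    decoded = _decoded(decisions)
    events = a.segment_mental_events(decoded.decisions)
    m = a.compute_attention_metrics(decoded, events)
    b = m.per_state["Breath"]
    assert b.n_events == 2
    assert b.mean_duration_s == pytest.approx(3.5)
    assert b.sd_duration_s == pytest.approx(0.70710678, abs=1e-6)


def test_single_event_sd_undefined():
    decoded = _decoded(["Breath"] * 5 + ["MW", "Self"] * 2)
    events = a.segment_mental_events(decoded.decisions)
    m = a.compute_attention_metrics(decoded, events)
    assert m.per_state["Breath"].n_events == 1
    assert m.per_state["Breath"].sd_duration_s is None
    assert m.per_state["Self"].n_events == 0
    assert m.per_state["Self"].mean_duration_s is None


def test_mismatched_events_rejected():
    decoded = _decoded(["Breath"] * 6)
    with pytest.raises(ValueError, match="does not match"):
        a.compute_attention_metrics(decoded, [MentalEvent("MW", 0, 3)])


def test_percent_time_invariant_to_tr_but_durations_scale():
    decisions = ["Breath"] * 6 + ["MW"] * 4
    m1 = a.compute_attention_metrics(
        _decoded(decisions, 1.0), a.segment_mental_events(decisions)
    )
    m2 = a.compute_attention_metrics(
        _decoded(decisions, 2.0), a.segment_mental_events(decisions)
    )
    assert m1.per_state["Breath"].percent_time == m2.per_state["Breath"].percent_time
    assert m2.per_state["Breath"].mean_duration_s == 2 * m1.per_state["Breath"].mean_duration_s


def test_events_only_variant_counts_event_trs():
    decisions = ["Breath"] * 3 + ["MW", "Self"] + ["Breath"] * 2  # short runs unassigned
    decoded = _decoded(decisions)
    events = a.segment_mental_events(decoded.decisions)
    m = a.compute_attention_metrics(decoded, events, events_only=True)
    assert m.per_state["Breath"].percent_time == pytest.approx(100 * 3 / 7)
    assert m.per_state["MW"].percent_time == 0.0


# ---------------------------------------------------------------------------
# group statistics


def test_one_sample_ttest_hand_computed():
    stats = a.group_accuracy_ttest([30.0, 40.0, 50.0], 20.0)
    assert stats.t == pytest.approx(3.4641016, abs=1e-6)
    assert stats.df == 2
    assert stats.cohens_d == pytest.approx(2.0)
    assert stats.estimate == pytest.approx(40.0)


def test_one_sample_ttest_symmetric_two_points():
    stats = a.group_accuracy_ttest([21.0, 19.0], 20.0)
    assert stats.t == pytest.approx(0.0)
    assert stats.p == pytest.approx(1.0)
    assert stats.cohens_d == pytest.approx(0.0)


def test_one_sample_ttest_zero_variance_errors():
    with pytest.raises(ValueError, match="zero variance"):
        a.group_accuracy_ttest([20.0, 20.0, 20.0], 20.0)


def test_ttest_matches_textbook_formula_oracle():
    rng = np.random.default_rng(70)
    for _ in range(25):
        vals = rng.normal(50, 10, size=rng.integers(3, 20))
        ref = float(rng.normal(50, 5))
        stats = a.group_accuracy_ttest(vals, ref)
        n, mean, sd = len(vals), vals.mean(), vals.std(ddof=1)
        t_oracle = (mean - ref) / (sd / np.sqrt(n))
        assert stats.t == pytest.approx(t_oracle, abs=1e-10)
        assert stats.cohens_d == pytest.approx((mean - ref) / sd, abs=1e-10)


def test_fisher_z_symmetric_correlations():
    stats = a.fisher_z_group_test([0.5, 0.0, -0.5])
    assert stats.estimate == pytest.approx(0.0, abs=1e-12)
    assert stats.t == pytest.approx(0.0, abs=1e-12)
    assert stats.p == pytest.approx(1.0)


def test_fisher_z_degenerate_inputs():
    with pytest.raises(ValueError):
        a.fisher_z_group_test([0.0, 0.0, 0.0])  # zero variance
    with pytest.raises(ValueError):
        a.fisher_z_group_test([0.9])  # n < 2
    with pytest.raises(ValueError, match="infinite"):
        a.fisher_z_group_test([0.5, 1.0])


def test_fisher_z_excludes_missing_with_log(caplog):
    import logging

    with caplog.at_level(logging.INFO, logger="attnstates.metrics"):
        stats = a.fisher_z_group_test([0.5, np.nan, 0.2, -0.1])
    assert stats.n == 3
    assert any("excluding 1" in r.message for r in caplog.records)


def _metrics(subject_id, breath, mw=20.0, self_pct=10.0):
    def sm(p):
        return StateMetrics(percent_time=p, n_events=1, mean_duration_s=3.0, sd_duration_s=None)

    return a.AttentionMetrics(
        subject_id=subject_id,
        per_state={"Breath": sm(breath), "MW": sm(mw), "Self": sm(self_pct)},
    )


def test_paired_breath_vs_other_hand_computed():
    ms = [_metrics("s1", 60.0, mw=20.0), _metrics("s2", 50.0, mw=30.0)]
    stats = a.compare_breath_vs_other(ms, "MW")
    assert stats.t == pytest.approx(3.0)
    assert stats.df == 1
    assert stats.estimate == pytest.approx(30.0)


def test_paired_identical_vectors_error():
    ms = [_metrics("s1", 50.0, mw=50.0), _metrics("s2", 40.0, mw=40.0)]
    with pytest.raises(ValueError, match="zero variance"):
        a.compare_breath_vs_other(ms, "MW")


def test_paired_symmetric_differences_t_zero():
    ms = [
        _metrics("s1", 30.0, mw=20.0),  # diff +10
        _metrics("s2", 20.0, mw=30.0),  # diff -10
        _metrics("s3", 25.0, mw=25.0),  # diff 0
    ]
    stats = a.compare_breath_vs_other(ms, "MW")
    assert stats.t == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# recovery score


def test_recovery_score_identity_and_disjoint():
    seq = np.array(["Breath", "MW", "Self"] * 4)
    truth = MeditationTruth(seq, sticky_chain((0.5, 0.3, 0.2)), {})
    assert a.sequence_recovery_score(_decoded(seq), truth) == 1.0
    flipped = np.array(["MW", "Self", "Breath"] * 4)
    assert a.sequence_recovery_score(_decoded(flipped), truth) == 0.0


def test_recovery_score_random_guessing_near_third():
    rng = np.random.default_rng(71)
    n = 6000
    truth_seq = np.asarray(a.MEDITATION_STATES)[rng.integers(0, 3, n)]
    guess = np.asarray(a.MEDITATION_STATES)[rng.integers(0, 3, n)]
    truth = MeditationTruth(truth_seq, sticky_chain((0.5, 0.3, 0.2)), {})
    score = a.sequence_recovery_score(_decoded(guess), truth)
    assert abs(score - 1.0 / 3.0) < 0.025


def test_recovery_score_length_mismatch():
    truth = MeditationTruth(
        np.array(["Breath"] * 5), sticky_chain((0.5, 0.3, 0.2)), {}
    )
    with pytest.raises(ValueError):
        a.sequence_recovery_score(_decoded(["Breath"] * 4), truth)
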