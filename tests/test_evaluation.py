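import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faceattn import (
    cross_group_eval,
    leave_one_participant_out,
    make_model_factory,
    metric_suite,
    participant_specific_eval,
    summarize,
)
from faceattn.errors import InsufficientDataError
from faceattn.features import FeatureMatrix


def _p1_vectors():
    """Counts for the illustrative participant: 200 attention samples with 4
    misclassified, 30 inattention with 6 misclassified."""
    truth = np.array([1] * 200 + [0] * 30)
    pred = np.array([1] * 196 + [0] * 4 + [0] * 24 + [1] * 6)
    return truth, pred


def test_confusion_arithmetic_for_the_published_participant():
    truth, pred = _p1_vectors()
    res = metric_suite(truth, pred)
    assert res.acc == pytest.approx(220 / 230)
    assert round(res.acc, 3) == 0.957
    np.testing.assert_array_equal(res.confusion, [[196, 4], [6, 24]])
    # row sums are the true class counts; entries sum to n_test
    assert res.confusion.sum() == res.n_test == 230
    np.testing.assert_array_equal(res.confusion.sum(axis=1), [200, 30])


def test_perfect_prediction():
    truth = np.array([1, 0, 1, 0])
    res = metric_suite(truth, truth, scores=truth.astype(float))
    assert res.acc == res.auc == res.f1 == 1.0


def test_constant_scores_give_half_auc():
    truth = np.array([1, 0, 1, 0])
    res = metric_suite(truth, truth, scores=np.zeros(4))
    assert res.auc == 0.5


def test_single_class_truth_auc_undefined_but_acc_f1_returned():
    truth = np.ones(5, dtype=int)
    with pytest.warns(UserWarning, match="AUC undefined"):
        res = metric_suite(truth, truth, scores=np.arange(5.0))
    assert res.auc is None
    assert res.acc == 1.0 and res.f1 == 1.0


def _brute_force_auc(truth, scores):
    """O(n^2) pairwise rule: P(attention score > inattention score), ties 1/2."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    truth=st.lists(st.integers(0, 1), min_size=4, max_size=40).filter(
        lambda t: 0 < sum(t) < len(t)
    ),
    data=st.data(),
)
def test_auc_equals_pairwise_oracle(truth, data):
    scores = data.draw(
        st.lists(
            st.sampled_from([0.0, 0.25, 0.5, 1.0, -1.0, 2.0]),
            min_size=len(truth),
            max_size=len(truth),
        )
    )
    truth = np.array(truth)
    res = metric_suite(truth, truth, scores=np.array(scores))
    assert res.auc == pytest.approx(_brute_force_auc(truth, scores), abs=1e-12)


def test_summary_averaging_matches_hand_computed_mean():
    truth, pred = _p1_vectors()
    r1 = metric_suite(truth, pred)
    r2 = metric_suite(np.array([1, 0]), np.array([1, 1]))
    s = summarize([r1, r2])
    assert s["acc_mean"] == pytest.approx((r1.acc + r2.acc) / 2)
    assert s["n"] == 2


def _planted_matrix(
    rng, pids, shift=6.0, n_rows=60, n_features=25, scramble=(), direction_sign=1.0
):
    """Participants whose inattention rows are shifted on every feature.
    Participants in ``scramble`` shift their *attention* rows instead, so
    their attention looks like everyone else's inattention — disjoint
    behaviors that no pooled model can fit."""
    parts = []
    for pid in pids:
        y = (rng.random(n_rows) < 0.8).astype(int)
        X = rng.normal(100.0, 2.0, size=(n_rows, n_features))
        shifted_class = 1 if pid in scramble else 0
        X[y == shifted_class] += direction_sign * shift
        parts.append(
            FeatureMatrix(X, np.arange(n_features), y, np.array([pid] * n_rows, dtype=object))
        )
    from faceattn.features import concat_matrices

    return concat_matrices(parts)


@pytest.fixture(scope="module")
def factory():
    return make_model_factory("svm", n_features=10)


def test_participant_specific_near_perfect_on_planted_signal(rng, factory):
    m = _planted_matrix(rng, ["P1", "P2"])
    per, avg = participant_specific_eval(m, factory, seed=0, n_repeats=3)
    assert set(per) == {"P1", "P2"}
    assert avg["acc_mean"] > 0.9
    # averaging equals recomputing the mean from the stored per-participant table
    hand = np.mean([summarize(res)["acc_mean"] for res in per.values()])
    assert avg["acc_mean"] == pytest.approx(hand)


def test_participant_specific_shuffled_labels_chance_auc(rng, factory):
    m = _planted_matrix(rng, ["P1"], n_rows=120)
    m.labels = rng.permutation(m.labels)
    m.X = rng.normal(100.0, 2.0, size=m.X.shape)  # remove all signal
    _, avg = participant_specific_eval(m, factory, seed=0, n_repeats=5)
    assert abs(avg["auc_mean"] - 0.5) < 0.25


def test_participant_missing_a_class_is_excluded(rng, factory):
    m = _planted_matrix(rng, ["P1", "P2"])
    m.labels[m.participant_ids == "P2"] = 1
    with pytest.warns(UserWarning, match="P2"):
        per, _ = participant_specific_eval(m, factory, seed=0, n_repeats=2)
    assert set(per) == {"P1"}


class TestLeaveOneParticipantOut:
    def test_fold_count_equals_participant_count(self, rng, factory):
        m = _planted_matrix(rng, ["P1", "P2", "P3"])
        per, _ = leave_one_participant_out(m, factory, seed=0)
        assert set(per) == {"P1", "P2", "P3"}

    def test_exchangeable_participants_generalize(self, rng, factory):
        """Participants drawn from one distribution: LOPO close to the
        participant-specific level."""
        m = _planted_matrix(rng, ["P1", "P2", "P3"])
        _, lopo = leave_one_participant_out(m, factory, seed=0)
        _, ps = participant_specific_eval(m, factory, seed=0, n_repeats=3)
        assert lopo["acc_mean"] > 0.9
        assert abs(lopo["acc_mean"] - ps["acc_mean"]) < 0.1

    def test_disjoint_behaviors_break_generalization(self, rng, factory):
        """Half the cohort carries the opposite feature shift: each held-out
        participant is modeled by a majority that disagrees with it, so LOPO
        collapses while participant-specific stays high."""
        m = _planted_matrix(
            rng, ["P1", "P2", "P3", "P4"], scramble=("P2", "P4"), n_rows=80
        )
        _, lopo = leave_one_participant_out(m, factory, seed=0)
        _, ps = participant_specific_eval(m, factory, seed=0, n_repeats=3)
        assert ps["acc_mean"] > lopo["acc_mean"]
        assert lopo["auc_mean"] < 0.75

    def test_needs_two_participants(self, rng, factory):
        with pytest.raises(InsufficientDataError):
            leave_one_participant_out(_planted_matrix(rng, ["P1"]), factory)


class TestCrossGroup:
    def test_identical_groups_symmetric_and_iterations_honored(self, rng, factory):
        pids_a = ["A1", "A2", "A3", "A4", "A5"]
        pids_b = ["B1", "B2", "B3", "B4", "B5"]
        a = _planted_matrix(rng, pids_a, n_rows=40)
        b = _planted_matrix(rng, pids_b, n_rows=40)
        cells, summary = cross_group_eval(a, b, factory, iterations=4, seed=0)
        assert all(len(v) == 4 for v in cells.values())
        accs = [summary[c]["acc_mean"] for c in ("A->A", "A->B", "B->A", "B->B")]
        assert max(accs) - min(accs) < 0.15  # statistically indistinguishable

    def test_orthogonal_groups_within_beats_cross(self, rng, factory):
        a = _planted_matrix(rng, ["A1", "A2", "A3", "A4"], n_rows=50)
        b = _planted_matrix(
            rng, ["B1", "B2", "B3", "B4"], n_rows=50,
            scramble=("B1", "B2", "B3", "B4"),
        )
        _, summary = cross_group_eval(a, b, factory, iterations=4, seed=1)
        within = (summary["A->A"]["auc_mean"] + summary["B->B"]["auc_mean"]) / 2
        cross = (summary["A->B"]["auc_mean"] + summary["B->A"]["auc_mean"]) / 2
        assert within > cross

    def test_group_too_small(self, rng, factory):
        a = _planted_matrix(rng, ["A1"])
        with pytest.raises(InsufficientDataError):
            cross_group_eval(a, a, factory, iterations=1, seed=0)
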