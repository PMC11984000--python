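import json

import numpy as np
import pytest

from vidability.cotrain import (
    CotrainConfig,
    FileQueueOracle,
    LabeledSet,
    OracleUnavailable,
    SimulatedOracle,
    ViewPair,
    cotrain,
    evaluate,
    precision_at_k,
    predict,
    resolve_labels,
    select_confident,
)
from vidability.synthetic import SyntheticConfig, extract_view_features, generate_corpus


class TestSelectConfident:
    def test_direct_thresholding(self):
        pos, neg = select_confident({"a": 0.9, "b": 0.6, "c": 0.2}, 0.65)
        assert pos == {"a"} and neg == {"c"}

    def test_threshold_one_selects_only_certainty(self):
        pos, neg = select_confident({"a": 0.99, "b": 0.01}, 1.0)
        assert pos == set() and neg == set()
        pos, neg = select_confident({"a": 1.0, "b": 0.0}, 1.0)
        assert pos == {"a"} and neg == {"b"}

    def test_boundary_is_inclusive(self):
        pos, neg = select_confident({"a": 0.65, "b": 0.35}, 0.65)
        assert pos == {"a"} and neg == {"b"}

    def test_threshold_at_or_below_half_rejected(self):
        with pytest.raises(ValueError):
            select_confident({"a": 0.9}, 0.5)

    def test_raising_threshold_never_enlarges_selections(self):
        rng = np.random.default_rng(0)
        probs = {f"v{i}": float(p) for i, p in enumerate(rng.uniform(size=50))}
        previous_pos, previous_neg = select_confident(probs, 0.51)
        for t in (0.6, 0.7, 0.8, 0.95, 1.0):
            pos, neg = select_confident(probs, t)
            assert pos <= previous_pos and neg <= previous_neg
            assert not (pos & neg)
            previous_pos, previous_neg = pos, neg


class TestResolveLabels:
    def oracle(self, answers):
        return SimulatedOracle(answers)

    def test_cross_view_agreement_needs_no_oracle(self):
        labels, calls = resolve_labels({"a"}, set(), {"a"}, set(), self.oracle({}))
        assert labels == {"a": (1, "view-agreement")} and calls == []

    def test_conflict_goes_to_the_oracle(self):
        labels, calls = resolve_labels({"a"}, set(), set(), {"a"}, self.oracle({"a": 0}))
        assert labels == {"a": (0, "oracle")}
        assert len(calls) == 1 and calls[0]["video_id"] == "a"

    def test_single_view_confidence_is_not_moved(self):
        labels, calls = resolve_labels({"a"}, set(), set(), set(), self.oracle({}))
        assert labels == {} and calls == []

    def test_overlapping_selections_within_a_view_rejected(self):
        with pytest.raises(ValueError):
            resolve_labels({"a"}, {"a"}, set(), set(), self.oracle({}))


class TestSimulatedOracle:
    def test_perfect_oracle_returns_truth(self):
        oracle = SimulatedOracle({"a": 1, "b": 0})
        assert oracle.query("a") == 1 and oracle.query("b") == 0

    def test_error_rate_is_deterministic_and_order_independent(self):
        truth = {f"v{i}": i % 2 for i in range(50)}
        o1 = SimulatedOracle(truth, error_rate=0.3, seed=9)
        o2 = SimulatedOracle(truth, error_rate=0.3, seed=9)
        forward = [o1.query(v) for v in sorted(truth)]
        backward = [o2.query(v) for v in sorted(truth, reverse=True)][::-1]
        assert forward == backward
        flipped = sum(forward[i] != truth[v] for i, v in enumerate(sorted(truth)))
        assert 0 < flipped < 50


class TestFileQueueOracle:
    def test_unanswered_query_is_queued(self, tmp_path):
        oracle = FileQueueOracle(tmp_path / "queue")
        with pytest.raises(OracleUnavailable):
            oracle.query("v1", None, (0.9, 0.2))
        assert "v1" in (tmp_path / "queue" / "pending.csv").read_text()

    def test_answered_query_is_served(self, tmp_path):
        qdir = tmp_path / "queue"
        qdir.mkdir()
        (qdir / "answers.csv").write_text("video_id,label\nv1,1\n")
        assert FileQueueOracle(qdir).query("v1") == 1


class _FixedProbModel:
    """Stub learner whose positive-class probability is the feature value."""

    def predict_proba(self, X):
        p = np.asarray(X, dtype=float)[:, 0]
        return np.column_stack([1 - p, p])


def _stub_result():
    from vidability.cotrain import CotrainResult

    return CotrainResult(_FixedProbModel(), _FixedProbModel(), LabeledSet())


@pytest.mark.parametrize(
    "p_meta,p_content,label,combined",
    [(0.8, 0.6, 1, 0.7), (0.5, 0.5, 1, 0.5), (0.2, 0.3, 0, 0.25)],
)
def test_predict_combines_views_by_mean_probability(p_meta, p_content, label, combined):
    views = {"x": ViewPair(np.array([p_meta]), np.array([p_content]))}
    out = predict(_stub_result(), views)
    assert out["x"][0] == label
    assert out["x"][1] == pytest.approx(combined)


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([0, 1, 1], [0, 1, 1], [0.1, 0.9, 0.8])
        assert m.weighted_precision == m.weighted_recall == m.weighted_f1 == 1.0
        assert m.auc == 1.0

    def test_hand_computed_confusion_matrix(self):
        m = evaluate([1, 1, 0, 0], [1, 0, 0, 0])
        assert m.weighted_precision == pytest.approx(5 / 6)
        assert m.weighted_recall == pytest.approx(0.75)
        assert m.weighted_f1 == pytest.approx((2 / 3 + 0.8) / 2)
        assert m.per_class[1]["support"] == 2

    def test_auc_by_pair_enumeration(self):
        m = evaluate([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert m.auc == pytest.approx(0.75)

    def test_single_class_truth_gives_metrics_but_no_auc(self):
        with pytest.warns(UserWarning, match="AUC"):
            m = evaluate([1, 1], [1, 0], [0.9, 0.2])
        assert m.auc is None
        assert m.per_class[1]["recall"] == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 0], [1])


class TestPrecisionAtK:
    def test_single_list(self):
        per_query, pooled = precision_at_k([[1, 0, 1, 0]], 2)
        assert per_query == [0.5] and pooled == 0.5

    def test_pooled_fraction_over_twenty_queries(self):
        lists = [[1] * 8 + [0] * 2] * 4 + [[1] * 7 + [0] * 3] * 16
        per_query, pooled = precision_at_k(lists, 10)
        assert sum(p * 10 for p in per_query) == 144
        assert pooled == pytest.approx(0.72)

    def test_all_irrelevant(self):
        assert precision_at_k([[0, 0, 0]], 3)[1] == 0.0

    def test_short_list_rejected(self):
        with pytest.raises(ValueError):
            precision_at_k([[1, 0]], 3)


@pytest.fixture(scope="module")
def tiny_corpus():
    config = SyntheticConfig(n_videos=80, seed=3)
    units, truth = generate_corpus(config)
    views = extract_view_features(units, truth)
    ids = sorted(views)
    labeled = {v: truth.labels[v] for v in ids[:20]}
    # the seed pool must contain both classes
    assert set(labeled.values()) == {0, 1}
    return views, truth, labeled, ids


class TestCotrainLoop:
    def config(self, **kw):
        return CotrainConfig(seed=3, **kw)

    def test_empty_unlabeled_pool_trains_on_seeds_only(self, tiny_corpus):
        views, truth, labeled, ids = tiny_corpus
        L = LabeledSet.from_views(views, labeled)
        result = cotrain(L, {}, self.config(), SimulatedOracle(truth.labels))
        assert result.halt_reason == "U_empty"
        assert result.oracle_call_count == 0
        assert len(result.labeled_prime) == len(labeled)

    def test_unreachable_threshold_halts_and_falls_back(self, tiny_corpus):
        views, truth, labeled, ids = tiny_corpus
        L = LabeledSet.from_views(views, labeled)
        U = {v: views[v] for v in ids[20:]}
        result = cotrain(L, U, self.config(confidence_threshold=1.0),
                         SimulatedOracle(truth.labels))
        assert result.halt_reason == "no_additions"
        assert result.oracle_call_count == 0
        fallback = [v for v, e in result.labeled_prime.entries.items() if e.provenance == "fallback"]
        assert sorted(fallback) == ids[20:]

    def test_label_low_policy_marks_leftovers_low(self, tiny_corpus):
        views, truth, labeled, ids = tiny_corpus
        L = LabeledSet.from_views(views, labeled)
        U = {v: views[v] for v in ids[20:]}
        result = cotrain(L, U, self.config(confidence_threshold=1.0, leftover_policy="label_low"),
                         SimulatedOracle(truth.labels))
        assert all(result.labeled_prime.entries[v].label == 0 for v in ids[20:])

    def test_seed_labels_survive_and_enlarged_set_contains_them(self, tiny_corpus):
        views, truth, labeled, ids = tiny_corpus
        L = LabeledSet.from_views(views, labeled)
        U = {v: views[v] for v in ids[20:]}
        result = cotrain(L, U, self.config(), SimulatedOracle(truth.labels))
        for vid, label in labeled.items():
            entry = result.labeled_prime.entries[vid]
            assert entry.label == label and entry.provenance == "seed"
        assert len(result.labeled_prime) == len(views)

    def test_oracle_calls_bounded_by_unlabeled_pool(self, tiny_corpus):
        views, truth, labeled, ids = tiny_corpus
        L = LabeledSet.from_views(views, labeled)
        U = {v: views[v] for v in ids[20:]}
        result = cotrain(L, U, self.config(), SimulatedOracle(truth.labels, error_rate=0.2, seed=1))
        assert result.oracle_call_count <= len(U)
        audited = [c["video_id"] for e in result.audit for c in e.get("oracle", [])]
        assert len(audited) == result.oracle_call_count

    def test_identical_seed_gives_identical_audit_and_labels(self, tiny_corpus):
        views, truth, labeled, ids = tiny_corpus
        runs = []
        for _ in range(2):
            L = LabeledSet.from_views(views, labeled)
            U = {v: views[v] for v in ids[20:]}
            result = cotrain(L, U, self.config(), SimulatedOracle(truth.labels, seed=5))
            runs.append((json.dumps(result.audit), result.labeled_prime.labels()))
        assert runs[0] == runs[1]

    def test_single_class_seed_pool_rejected(self, tiny_corpus):
        views, truth, labeled, ids = tiny_corpus
        ones = {v: 1 for v in list(labeled)[:5]}
        L = LabeledSet.from_views(views, ones)
        with pytest.raises(ValueError, match="both classes"):
            cotrain(L, {}, self.config(), SimulatedOracle(truth.labels))

    def test_missing_view_rejected(self, tiny_corpus):
        views, truth, labeled, ids = tiny_corpus
        L = LabeledSet.from_views(views, labeled)
        U = {"broken": (views[ids[20]].meta, None)}
        with pytest.raises(ValueError, match="view"):
            cotrain(L, U, self.config(), SimulatedOracle(truth.labels))


def test_seed_entries_cannot_be_relabeled():
    L = LabeledSet()
    L.add("v", np.zeros(2), np.zeros(2), 1, "seed")
    with pytest.raises(ValueError, match="seed"):
        L.add("v", np.zeros(2), np.zeros(2), 0, "oracle")


class TestSeparableCorpusRun:
    def test_cotraining_matches_or_beats_each_single_view_baseline(self, separable_run):
        wf1 = separable_run["metrics"].weighted_f1
        for name, metrics in separable_run["baselines"].items():
            assert wf1 >= metrics.weighted_f1, name

    def test_held_out_error_non_increasing_within_tolerance(self, separable_run):
        errors = separable_run["eval_errors"]
        assert len(errors) >= 2
        for previous, current in zip(errors, errors[1:]):
            assert current <= previous + 0.02

    def test_separable_recovery_reaches_high_f1(self, separable_run):
        assert separable_run["metrics"].weighted_f1 >= 0.90
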