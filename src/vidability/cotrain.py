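"""Human-in-the-loop co-training over the metadata and content views.

Two L2-regularized logistic classifiers, one per feature view, are trained
on the labeled pool and asked to score the unlabeled pool.  Predictions
confident beyond a threshold are compared across views: agreements are
auto-labeled, confident disagreements are sent to an oracle (the human
expert in production; a simulated expert in tests), and everything else
stays unlabeled for the next round.  The loop halts when the unlabeled
pool is empty, an iteration adds nothing, or an iteration cap is reached;
leftovers are then labeled by a configurable fallback policy.

Provenance is tracked for every label (seed, view-agreement, oracle,
fallback) and an audit log records each iteration, so a run is fully
reproducible from its config and seed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ViewPair",
    "LabeledEntry",
    "LabeledSet",
    "CotrainConfig",
    "CotrainResult",
    "make_learner",
    "Oracle",
    "OracleUnavailable",
    "SimulatedOracle",
    "FileQueueOracle",
    "InteractiveOracle",
    "select_confident",
    "resolve_labels",
    "cotrain",
    "predict",
    "EvalMetrics",
    "evaluate",
    "precision_at_k",
]

PROVENANCES = ("seed", "view-agreement", "oracle", "fallback")


class ViewPair(NamedTuple):
    """Both feature vectors for one video."""

    meta: np.ndarray
    content: np.ndarray


class LabeledEntry(NamedTuple):
    meta: np.ndarray
    content: np.ndarray
    label: int
    provenance: str


class LabeledSet:
    """Mapping video_id -> (both views, label, provenance).

    Seed entries are protected: once added with provenance ``seed`` an
    entry can never be relabeled.
    """

    def __init__(self, entries: Optional[Mapping[str, LabeledEntry]] = None):
        self.entries: dict[str, LabeledEntry] = dict(entries or {})

    @classmethod
    def from_views(cls, views: Mapping[str, ViewPair], labels: Mapping[str, int],
                   provenance: str = "seed") -> "LabeledSet":
        out = cls()
        for vid in sorted(labels):
            pair = views[vid]
            out.add(vid, pair.meta, pair.content, int(labels[vid]), provenance)
        return out

    def add(self, vid: str, meta, content, label: int, provenance: str) -> None:
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        if label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {label!r}")
        existing = self.entries.get(vid)
        if existing is not None and existing.provenance == "seed":
            raise ValueError(f"seed label for {vid!r} cannot be changed")
        self.entries[vid] = LabeledEntry(
            np.asarray(meta, dtype=float), np.asarray(content, dtype=float), label, provenance
        )

    def ids(self) -> list[str]:
        return sorted(self.entries)

    def labels(self) -> dict[str, int]:
        return {vid: e.label for vid, e in self.entries.items()}

    def matrices(self, exclude_provenance: Sequence[str] = ()) -> tuple:
        """(X_meta, X_content, y) over entries, in sorted-id order."""
        ids = [v for v in self.ids() if self.entries[v].provenance not in exclude_provenance]
        X_meta = np.vstack([self.entries[v].meta for v in ids])
        X_content = np.vstack([self.entries[v].content for v in ids])
        y = np.array([self.entries[v].label for v in ids], dtype=int)
        return X_meta, X_content, y

    def copy(self) -> "LabeledSet":
        return LabeledSet(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, vid) -> bool:
        return vid in self.entries


@dataclass(frozen=True)
class CotrainConfig:
    """Co-training hyperparameters.

    ``confidence_threshold`` must exceed 0.5, else the confident-positive
    and confident-negative sets could overlap.  The default of 0.65 worked
    well on real video corpora; ``max_iterations`` is a safety cap (runs
    typically converge in far fewer rounds).
    """

    confidence_threshold: float = 0.65
    max_iterations: int = 50
    base_learner: str = "logistic_l2"
    l2_strength: float = 1.0
    leftover_policy: str = "mean_probability_vote"
    seed: int = 0

    def __post_init__(self):
        if not (0.5 < self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must lie in (0.5, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.l2_strength <= 0:
            raise ValueError("l2_strength must be positive")
        if self.leftover_policy not in ("label_low", "mean_probability_vote"):
            raise ValueError("leftover_policy must be 'label_low' or 'mean_probability_vote'")


def make_learner(config: CotrainConfig):
    """Default per-view learner: mean imputation with missingness
    indicators, z-scoring, then L2 logistic regression.  Any object with
    ``fit`` and two-column ``predict_proba`` conforms to the contract.
    """
    if config.base_learner != "logistic_l2":
        raise ValueError(f"unknown base_learner {config.base_learner!r}")
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="mean", add_indicator=True, keep_empty_features=True)),
            ("scale", StandardScaler()),
            (
                "logreg",
                LogisticRegression(  # default penalty is the ridge (L2) one
                    C=1.0 / config.l2_strength,
                    solver="liblinear",
                    random_state=config.seed % (2**31),
                ),
            ),
        ]
    )


# ---------------------------------------------------------------------------
# Oracles

class OracleUnavailable(RuntimeError):
    """The oracle cannot answer now (e.g. the answer queue has no entry)."""


class Oracle:
    """Expert arbitration contract for cross-view conflicts."""

    def query(self, video_id: str, views: ViewPair, predictions: tuple) -> int:
        raise NotImplementedError


class SimulatedOracle(Oracle):
    """Ground-truth oracle with an optional per-query error rate.

    Deterministic given ``seed``: the flip decision for a video depends
    only on (seed, video_id), not on query order.
    """

    def __init__(self, truth: Mapping[str, int], error_rate: float = 0.0, seed: int = 0):
        if not (0.0 <= error_rate <= 1.0):
            raise ValueError("error_rate must lie in [0,1]")
        self.truth = dict(truth)
        self.error_rate = error_rate
        self.seed = seed

    def query(self, video_id, views=None, predictions=None) -> int:
        label = int(self.truth[video_id])
        if self.error_rate > 0.0:
            rng = np.random.default_rng([self.seed, zlib.crc32(video_id.encode())])
            if rng.random() < self.error_rate:
                label = 1 - label
        return label


class FileQueueOracle(Oracle):
    """File-based oracle protocol for asynchronous expert annotation.

    Unanswered queries are appended to ``pending.csv`` (video_id plus the
    conflicting per-view probabilities) and :class:`OracleUnavailable` is
    raised; answers are read from ``answers.csv`` (header
    ``video_id,label``).
    """

    def __init__(self, queue_dir):
        from pathlib import Path

        self.dir = Path(queue_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.pending = self.dir / "pending.csv"
        self.answers = self.dir / "answers.csv"

    def _read_answers(self) -> dict:
        import csv

        if not self.answers.exists():
            return {}
        with open(self.answers, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            return {row["video_id"]: int(row["label"]) for row in reader}

    def query(self, video_id, views=None, predictions=None) -> int:
        answers = self._read_answers()
        if video_id in answers:
            return answers[video_id]
        new_file = not self.pending.exists()
        with open(self.pending, "a", encoding="utf-8") as fh:
            if new_file:
                fh.write("video_id,prob_meta,prob_content\n")
            p1, p2 = predictions if predictions else ("", "")
            fh.write(f"{video_id},{p1},{p2}\n")
        raise OracleUnavailable(
            f"no answer for {video_id!r}; question appended to {self.pending}"
        )


class InteractiveOracle(Oracle):
    """Prompt a human on stdin for each conflict (0 or 1)."""

    def query(self, video_id, views=None, predictions=None) -> int:
        while True:
            raw = input(f"Label for video {video_id} (0=low, 1=high): ").strip()
            if raw in ("0", "1"):
                return int(raw)


# ---------------------------------------------------------------------------
# Core algorithm

def select_confident(prob_positive: Mapping[str, float], threshold: float):
    """Split ids into confident positives (p >= t) and confident negatives
    (1-p >= t); inclusive at the boundary, disjoint because t > 0.5."""
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    positives = {vid for vid, p in prob_positive.items() if p >= threshold}
    negatives = {vid for vid, p in prob_positive.items() if (1.0 - p) >= threshold}
    return positives, negatives


def resolve_labels(p1, n1, p2, n2, oracle: Oracle, views: Optional[Mapping[str, ViewPair]] = None,
                   probs: Optional[tuple] = None):
    """Combine the two views' confident selections.

    Cross-view agreement labels directly; confident disagreement goes to
    the oracle; ids confident in one view only are left unlabeled.  All
    oracle answers are gathered before anything is returned, so an oracle
    failure leaves no partial labeling.
    """
    if p1 & n1 or p2 & n2:
        raise ValueError("a view's positive and negative selections overlap")
    new_labels: dict[str, tuple] = {}
    for vid in sorted(p1 & p2):
        new_labels[vid] = (1, "view-agreement")
    for vid in sorted(n1 & n2):
        new_labels[vid] = (0, "view-agreement")
    conflicts = sorted((p1 & n2) | (p2 & n1))
    oracle_calls = []
    for vid in conflicts:
        pair = views.get(vid) if views else None
        pred = None
        if probs is not None:
            pred = (probs[0].get(vid), probs[1].get(vid))
        answer = int(oracle.query(vid, pair, pred))
        if answer not in (0, 1):
            raise ValueError(f"oracle returned {answer!r} for {vid!r}")
        oracle_calls.append({"video_id": vid, "label": answer})
        new_labels[vid] = (answer, "oracle")
    return new_labels, oracle_calls


@dataclass
class CotrainResult:
    classifier_meta: object
    classifier_content: object
    labeled_prime: LabeledSet
    audit: list = field(default_factory=list)
    oracle_call_count: int = 0
    halt_reason: str = ""
    config: Optional[CotrainConfig] = None


def _view_probs(model, views: Mapping[str, ViewPair], which: int) -> dict:
    ids = sorted(views)
    if not ids:
        return {}
    X = np.vstack([views[v][which] for v in ids])
    p = model.predict_proba(X)[:, 1]
    return dict(zip(ids, p))


def _combined_probs(result_meta, result_content, views) -> dict:
    pm = _view_probs(result_meta, views, 0)
    pc = _view_probs(result_content, views, 1)
    return {vid: 0.5 * (pm[vid] + pc[vid]) for vid in pm}


def cotrain(
    L: LabeledSet,
    U: Mapping[str, ViewPair],
    config: CotrainConfig,
    oracle: Oracle,
    eval_views: Optional[Mapping[str, ViewPair]] = None,
    eval_labels: Optional[Mapping[str, int]] = None,
    learner_factory: Optional[Callable[[CotrainConfig], object]] = None,
) -> CotrainResult:
    """Run the co-training loop; deterministic given ``config.seed``.

    ``eval_views``/``eval_labels`` (optional) are a held-out set whose
    combined-model error is recorded per iteration in the audit log; it is
    never used for training.
    """
    labels = set(L.labels().values())
    if labels != {0, 1}:
        raise ValueError("initial labeled set must contain both classes")
    for vid, pair in U.items():
        if pair[0] is None or pair[1] is None:
            raise ValueError(f"unit {vid!r} is missing a feature view")

    factory = learner_factory or make_learner
    L_prime = L.copy()
    remaining = {vid: ViewPair(np.asarray(p[0], float), np.asarray(p[1], float))
                 for vid, p in U.items()}
    audit: list[dict] = []
    oracle_call_count = 0
    halt_reason = "max_iterations"
    model_meta = model_content = None

    for iteration in range(1, config.max_iterations + 1):
        X_meta, X_content, y = L_prime.matrices()
        model_meta = factory(config).fit(X_meta, y)
        model_content = factory(config).fit(X_content, y)

        entry = {"iteration": iteration, "n_labeled": len(L_prime), "n_unlabeled": len(remaining)}
        if eval_views is not None and eval_labels is not None:
            combined = _combined_probs(model_meta, model_content, eval_views)
            err = float(
                np.mean([int(combined[v] >= 0.5) != eval_labels[v] for v in sorted(eval_views)])
            )
            entry["eval_error"] = err

        if not remaining:
            entry.update(p1=[], n1=[], p2=[], n2=[], agreements_pos=[], agreements_neg=[],
                         conflicts=[], oracle=[], added=0)
            audit.append(entry)
            halt_reason = "U_empty"
            break

        probs_meta = _view_probs(model_meta, remaining, 0)
        probs_content = _view_probs(model_content, remaining, 1)
        p1, n1 = select_confident(probs_meta, config.confidence_threshold)
        p2, n2 = select_confident(probs_content, config.confidence_threshold)
        new_labels, oracle_calls = resolve_labels(
            p1, n1, p2, n2, oracle, views=remaining, probs=(probs_meta, probs_content)
        )
        oracle_call_count += len(oracle_calls)

        for vid in sorted(new_labels):
            label, provenance = new_labels[vid]
            pair = remaining.pop(vid)
            L_prime.add(vid, pair.meta, pair.content, label, provenance)

        entry.update(
            p1=sorted(p1), n1=sorted(n1), p2=sorted(p2), n2=sorted(n2),
            agreements_pos=sorted(p1 & p2), agreements_neg=sorted(n1 & n2),
            conflicts=sorted({c["video_id"] for c in oracle_calls}),
            oracle=oracle_calls, added=len(new_labels),
        )
        audit.append(entry)

        if not remaining:
            halt_reason = "U_empty"
            break
        if not new_labels:
            halt_reason = "no_additions"
            break

    # Final classifiers reflect the converged labeled pool.
    X_meta, X_content, y = L_prime.matrices()
    model_meta = factory(config).fit(X_meta, y)
    model_content = factory(config).fit(X_content, y)

    # Fallback labeling of whatever could not be moved during the loop.
    if remaining:
        if config.leftover_policy == "label_low":
            fallback = {vid: 0 for vid in remaining}
        else:
            combined = _combined_probs(model_meta, model_content, remaining)
            fallback = {vid: int(combined[vid] >= 0.5) for vid in remaining}
        for vid in sorted(remaining):
            pair = remaining[vid]
            L_prime.add(vid, pair.meta, pair.content, fallback[vid], "fallback")

    audit.append({"halt_reason": halt_reason, "n_labeled": len(L_prime),
                  "oracle_call_count": oracle_call_count})
    return CotrainResult(
        classifier_meta=model_meta,
        classifier_content=model_content,
        labeled_prime=L_prime,
        audit=audit,
        oracle_call_count=oracle_call_count,
        halt_reason=halt_reason,
        config=config,
    )


def predict(result: CotrainResult, views: Mapping[str, ViewPair]) -> dict:
    """Combined prediction: mean of the two views' positive-class
    probabilities; label 1 iff the mean >= 0.5 (inclusive)."""
    for vid, pair in views.items():
        if pair[0] is None or pair[1] is None:
            raise ValueError(f"unit {vid!r} is missing a feature view")
    combined = _combined_probs(result.classifier_meta, result.classifier_content, views)
    return {vid: (int(p >= 0.5), float(p)) for vid, p in combined.items()}


# ---------------------------------------------------------------------------
# Evaluation metrics

@dataclass(frozen=True)
class EvalMetrics:
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    auc: Optional[float]
    per_class: dict  # class -> dict(precision, recall, f1, support)


def evaluate(y_true, y_pred, y_score=None) -> EvalMetrics:
    """Per-class and support-weighted precision/recall/F1, plus ROC AUC.

    AUC is the probability that a random positive outranks a random
    negative (ties count one half).  With a single-class truth vector the
    AUC is undefined and returned as ``None`` (with a warning); the other
    metrics are still computed.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0
    )
    total = support.sum()
    weights = support / total
    per_class = {
        int(c): {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
        for i, c in enumerate([0, 1])
    }
    auc = None
    if y_score is not None:
        if len(set(y_true.tolist())) < 2:
            warnings.warn("AUC undefined for single-class y_true; returning None")
        else:
            auc = float(roc_auc_score(y_true, np.asarray(y_score, dtype=float)))
    return EvalMetrics(
        weighted_precision=float(np.dot(weights, prec)),
        weighted_recall=float(np.dot(weights, rec)),
        weighted_f1=float(np.dot(weights, f1)),
        auc=auc,
        per_class=per_class,
    )


def precision_at_k(relevance_lists: Sequence[Sequence[int]], k: int):
    """P@K per ranked list plus the pooled fraction over all top-K slots."""
    if k < 1:
        raise ValueError("K must be positive")
    per_query = []
    total_relevant = 0
    for i, rel in enumerate(relevance_lists):
        if len(rel) < k:
            raise ValueError(f"relevance list {i} is shorter than K={k}")
        hits = sum(1 for r in rel[:k] if r)
        per_query.append(hits / k)
        total_relevant += hits
    if not per_query:
        raise ValueError("no relevance lists given")
    pooled = total_relevant / (k * len(per_query))
    return per_query, pooled
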