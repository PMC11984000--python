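import numpy as np
import pytest

from vidability.corpus_io import CorpusUnit, ScreenText, VideoRecord, VideoSignals
from vidability.cotrain import (
    CotrainConfig,
    LabeledSet,
    SimulatedOracle,
    cotrain,
    evaluate,
    make_learner,
    predict,
)
from vidability.synthetic import SyntheticConfig, extract_view_features, generate_corpus


@pytest.fixture
def small_units():
    """Three hand-written corpus units exercising degenerate fields."""
    return [
        CorpusUnit(
            VideoRecord(
                video_id="a1",
                title="Checking blood sugar",
                description="Finally, she checks the meter. In conclusion, test daily.",
                tags=["diabetes", "self-care"],
                duration_s=120.0,
                published_days=30.0,
                view_count=1000,
                like_count=50,
                comment_count=5,
                channel_view_count=100000,
                channel_subscriber_count=2000,
                channel_video_count=40,
                content_definition="HD",
            ),
            VideoSignals(
                video_id="a1",
                transcript="Insulin helps. Thus, ask the physician.",
                transcription_confidence=0.92,
                screen_texts=[ScreenText("slide one", 0.8), ScreenText("slide two", 0.6)],
                scene_count=6,
                object_count=3,
            ),
        ),
        CorpusUnit(
            VideoRecord(video_id="a2", title="", description="", tags=[], content_definition="SD"),
            None,
        ),
        CorpusUnit(
            VideoRecord(
                video_id="a3",
                title="Untagged",
                description="A short note.",
                tags=[],
                duration_s=45.5,
            ),
            VideoSignals(video_id="a3", transcript="", transcription_confidence=None,
                         screen_texts=[], scene_count=1, object_count=0),
        ),
    ]


def _split_run(n_labeled=60, n_unlabeled=600, n_eval=200, seed=7, **cfg_kwargs):
    config = SyntheticConfig(n_videos=n_labeled + n_unlabeled + n_eval, seed=seed, **cfg_kwargs)
    units, truth = generate_corpus(config)
    views = extract_view_features(units, truth)
    ids = sorted(views)
    lab, unl, ev = (
        ids[:n_labeled],
        ids[n_labeled : n_labeled + n_unlabeled],
        ids[n_labeled + n_unlabeled :],
    )
    return {
        "truth": truth,
        "views": views,
        "labeled_ids": lab,
        "unlabeled_ids": unl,
        "eval_ids": ev,
    }


@pytest.fixture(scope="session")
def separable_split():
    """The default separable two-view corpus: 60 seed-labeled, 600
    unlabeled, 200 held out; class-mean separation 2 SD, seed 7."""
    return _split_run()


@pytest.fixture(scope="session")
def separable_run(separable_split):
    """Co-training on the separable corpus with a perfect simulated
    oracle, plus each view's baseline trained on the seed labels alone."""
    s = separable_split
    truth, views = s["truth"], s["views"]
    L = LabeledSet.from_views(views, {v: truth.labels[v] for v in s["labeled_ids"]})
    U = {v: views[v] for v in s["unlabeled_ids"]}
    eval_views = {v: views[v] for v in s["eval_ids"]}
    eval_labels = {v: truth.labels[v] for v in s["eval_ids"]}
    config = CotrainConfig(seed=7)
    result = cotrain(
        L, U, config, SimulatedOracle(truth.labels),
        eval_views=eval_views, eval_labels=eval_labels,
    )
    pred = predict(result, eval_views)
    order = sorted(eval_views)
    y_true = [eval_labels[v] for v in order]
    combined_metrics = evaluate(
        y_true, [pred[v][0] for v in order], [pred[v][1] for v in order]
    )

    baselines = {}
    X_meta, X_content, y = L.matrices()
    for name, X, which in (("meta", X_meta, 0), ("content", X_content, 1)):
        model = make_learner(config).fit(X, y)
        X_eval = np.vstack([eval_views[v][which] for v in order])
        p = model.predict_proba(X_eval)[:, 1]
        baselines[name] = evaluate(y_true, (p >= 0.5).astype(int), p)

    return {
        "config": config,
        "L": L,
        "U": U,
        "result": result,
        "metrics": combined_metrics,
        "baselines": baselines,
        "eval_errors": [e["eval_error"] for e in result.audit if "eval_error" in e],
        **s,
    }
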