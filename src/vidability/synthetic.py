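"""Seeded synthetic corpora with known ground truth.

The generator realizes the two-view learning setting the classifier
assumes: a latent binary understandability label drives, conditionally
independently, (a) the creator-side metadata view and (b) the content
view.  Per-class feature settings are Gaussian with a configurable
class-mean separation (in SD units); count-valued features are rounded and
clipped at zero.  Description and transcript texts are assembled from
neutral filler sentences (verified free of every packaged lexicon phrase)
with cue phrases, active verbs, and medical terms planted at sentence
boundaries, so the text-feature extractors recover the planted counts
exactly.

Engagement counts follow a log-linear model
``log(count+1) = alpha + tau*label + beta*(2u-1) + noise`` where ``u`` is a
latent channel-maturity confounder; when confounding is enabled the same
``u`` also shifts the probability of a high label.  A separate generator,
:func:`generate_causal_units`, produces matching-ready units in which all
covariates are functions of ``u`` (pre-treatment), the clean setting for
validating the matching estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from vidability.corpus_io import CorpusUnit, ScreenText, VideoRecord, VideoSignals
from vidability.cotrain import ViewPair
from vidability.engagement import COVARIATE_NAMES, CausalUnit
from vidability.text_features import (
    DictionaryTagger,
    build_content_features,
    build_metadata_features,
    count_lexicon_phrases,
    count_medical_terms,
    medical_lexicons,
    summary_lexicon,
    transition_lexicon,
)

__all__ = [
    "TextPlantSpec",
    "PlantedText",
    "plant_text",
    "SyntheticConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_engagement",
    "generate_causal_units",
    "extract_view_features",
]


# ---------------------------------------------------------------------------
# Text planting

#: Planted active-voice verbs with their hand tags.  Disjoint from the
#: filler vocabulary and from every packaged lexicon.
_VERB_POOL = (
    ("checks", "VBZ"),
    ("explains", "VBZ"),
    ("reviews", "VBZ"),
    ("reviewed", "VBD"),
    ("showed", "VBD"),
    ("walked", "VBD"),
    ("check", "VBP"),
    ("explain", "VBP"),
)

_FILLER_SENTENCES = (
    "The daily chart.",
    "A glucose plan.",
    "The weekly routine.",
    "A simple note page.",
    "The care team topic.",
)

_TAG_MAP = {"she": "PRP", "they": "PRP"}
_TAG_MAP.update({verb: tag for verb, tag in _VERB_POOL})


@lru_cache(maxsize=1)
def _phrase_pools():
    """Phrases usable for exact planting: counted once by their own lexicon
    and zero times by the other cue lexicon (phrases on both lists, and
    phrases containing a word from the other list, are excluded)."""
    summ, trans = summary_lexicon(), transition_lexicon()
    pool_summary = sorted(
        p for p in summ.phrases
        if count_lexicon_phrases(p, summ) == 1 and count_lexicon_phrases(p, trans) == 0
    )
    pool_transition = sorted(
        p for p in trans.phrases
        if count_lexicon_phrases(p, trans) == 1 and count_lexicon_phrases(p, summ) == 0
    )
    return pool_summary, pool_transition


@lru_cache(maxsize=1)
def _medical_pool():
    return {lex.category: sorted(lex.phrases) for lex in medical_lexicons()}


@lru_cache(maxsize=1)
def _check_filler():
    text = " ".join(_FILLER_SENTENCES)
    assert count_lexicon_phrases(text, summary_lexicon()) == 0
    assert count_lexicon_phrases(text, transition_lexicon()) == 0
    assert count_medical_terms(text)[0] == 0


@dataclass(frozen=True)
class TextPlantSpec:
    """Requested exact counts for one planted text."""

    active_verbs: int = 0
    summary_phrases: int = 0
    transition_phrases: int = 0
    medical_terms: Union[int, Mapping[str, int]] = 0
    filler_sentences: int = 3
    #: Explicit phrases planted verbatim (may overlap both cue lexicons).
    extra_phrases: tuple = ()


@dataclass(frozen=True)
class PlantedText:
    text: str
    tag_map: dict
    spec: TextPlantSpec


def plant_text(spec: TextPlantSpec, rng: Optional[np.random.Generator] = None) -> PlantedText:
    """Assemble a text whose extracted counts equal the planted counts.

    Round-trip guarantees (against the packaged lexicons and the returned
    hand-tag map): active-verb, summary, transition, and medical counts all
    equal the spec.  ``extra_phrases`` are planted verbatim without that
    guarantee (useful for deliberately overlapping cue phrases).
    """
    for name in ("active_verbs", "summary_phrases", "transition_phrases", "filler_sentences"):
        if getattr(spec, name) < 0:
            raise ValueError(f"{name} must be nonnegative")
    _check_filler()
    pool_summary, pool_transition = _phrase_pools()
    med_pool = _medical_pool()

    sentences: list[str] = []
    for i in range(spec.filler_sentences):
        sentences.append(_FILLER_SENTENCES[i % len(_FILLER_SENTENCES)])
    for i in range(spec.active_verbs):
        verb, _ = _VERB_POOL[i % len(_VERB_POOL)]
        subject = "She" if i % 2 == 0 else "They"
        sentences.append(f"{subject} {verb} the chart.")
    for i in range(spec.summary_phrases):
        phrase = pool_summary[i % len(pool_summary)]
        sentences.append(f"{phrase.capitalize()}, the chart.")
    for i in range(spec.transition_phrases):
        phrase = pool_transition[i % len(pool_transition)]
        sentences.append(f"{phrase.capitalize()}, a note.")

    if isinstance(spec.medical_terms, int):
        if spec.medical_terms < 0:
            raise ValueError("medical_terms must be nonnegative")
        categories = sorted(med_pool)
        wanted = {c: 0 for c in categories}
        for i in range(spec.medical_terms):
            wanted[categories[i % len(categories)]] += 1
    else:
        wanted = {c: int(k) for c, k in spec.medical_terms.items()}
    for cat, k in sorted(wanted.items()):
        terms = med_pool[cat]
        for i in range(k):
            sentences.append(f"The {terms[i % len(terms)]} page.")

    for phrase in spec.extra_phrases:
        sentences.append(f"{phrase.capitalize()}, a note.")

    if rng is not None:
        order = rng.permutation(len(sentences))
        sentences = [sentences[i] for i in order]
    return PlantedText(text=" ".join(sentences), tag_map=dict(_TAG_MAP), spec=spec)


# ---------------------------------------------------------------------------
# Corpus generation

@dataclass(frozen=True)
class ClassSetting:
    """Class-conditional Normal(mean, sd) for one planted quantity."""

    mean_low: float
    mean_high: float
    sd: float

    def draw(self, rng: np.random.Generator, label: int) -> float:
        mean = self.mean_high if label else self.mean_low
        return float(rng.normal(mean, self.sd))


def _default_settings(sep: float) -> dict:
    """Per-quantity class-conditional settings at class-mean separation
    ``sep`` (in within-class SD units).  High-understandability videos
    carry more cue phrases and active verbs, fewer medical terms, shorter
    texts, fewer scenes, and higher transcription/OCR confidence."""
    return {
        "meta_active": ClassSetting(2.0, 2.0 + sep, 1.0),
        "meta_summary": ClassSetting(0.5, 0.5 + sep, 1.0),
        "meta_transition": ClassSetting(1.0, 1.0 + sep, 1.0),
        "meta_medical": ClassSetting(3.0 + sep, 3.0, 1.0),
        "meta_filler": ClassSetting(10.0, 10.0 - 2.0 * sep, 2.0),
        "content_active": ClassSetting(2.0, 2.0 + sep, 1.0),
        "content_summary": ClassSetting(0.5, 0.5 + sep, 1.0),
        "content_transition": ClassSetting(1.0, 1.0 + sep, 1.0),
        "content_medical": ClassSetting(3.0 + sep, 3.0, 1.0),
        "content_filler": ClassSetting(16.0, 16.0 - 3.0 * sep, 3.0),
        "transcription_conf": ClassSetting(0.75, 0.75 + 0.05 * sep, 0.05),
        "ocr_conf": ClassSetting(0.60, 0.60 + 0.10 * sep, 0.10),
        "scene_count": ClassSetting(30.0, 30.0 - 10.0 * sep, 10.0),
        "object_count": ClassSetting(12.0, 12.0 - 2.0 * sep, 2.0),
        "log_duration": ClassSetting(6.5, 6.5 - 0.4 * sep, 0.5),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``separation`` is the class-mean separation per planted feature in
    within-class SD units (2.0 realizes the separable two-view setting).
    ``confounding_strength`` couples the latent channel-maturity
    confounder ``u`` to the label probability on the logit scale (0 keeps
    treatment independent of the confounder).
    """

    n_videos: int = 700
    prevalence: float = 0.55
    separation: float = 2.0
    confounding_strength: float = 0.0
    oracle_error_rate: float = 0.0
    # Engagement model: log(count+1) = alpha + tau*label + beta*(2u-1) + eps
    alpha: tuple = (8.9, 3.2, 1.6)  # view, like, comment levels
    tau: float = 2.5
    beta_confounder: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in (0, 1]")
        if self.n_videos < 1:
            raise ValueError("n_videos must be positive")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """Latent state of a generated corpus (never shown to the learners
    except through seed labels and the oracle)."""

    labels: dict  # video_id -> 0/1
    u: dict  # video_id -> latent confounder in [0,1]
    tag_map: dict
    planted: dict  # video_id -> planted counts per view
    config: SyntheticConfig
    tau: Optional[float] = None


def _count(rng, setting: ClassSetting, label: int, minimum: int = 0) -> int:
    return max(minimum, int(round(setting.draw(rng, label))))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_corpus(config: SyntheticConfig):
    """Generate ``n_videos`` units with both views; returns (units, truth).

    Deterministic given ``config.seed`` (byte-identical on regeneration).
    """
    rng = np.random.default_rng(config.seed)
    settings = _default_settings(config.separation)
    base_logit = (
        math.inf if config.prevalence >= 1.0 else math.log(config.prevalence / (1 - config.prevalence))
    )

    units: list[CorpusUnit] = []
    labels: dict[str, int] = {}
    u_map: dict[str, float] = {}
    planted: dict[str, dict] = {}
    for i in range(config.n_videos):
        vid = f"v{i:05d}"
        u = float(rng.uniform())
        if math.isinf(base_logit):
            p_high = 1.0
        else:
            p_high = _sigmoid(base_logit + config.confounding_strength * (2 * u - 1))
        label = int(rng.uniform() < p_high)

        meta_counts = dict(
            active=_count(rng, settings["meta_active"], label),
            summary=_count(rng, settings["meta_summary"], label),
            transition=_count(rng, settings["meta_transition"], label),
            medical=_count(rng, settings["meta_medical"], label),
            filler=_count(rng, settings["meta_filler"], label, minimum=1),
        )
        content_counts = dict(
            active=_count(rng, settings["content_active"], label),
            summary=_count(rng, settings["content_summary"], label),
            transition=_count(rng, settings["content_transition"], label),
            medical=_count(rng, settings["content_medical"], label),
            filler=_count(rng, settings["content_filler"], label, minimum=1),
        )
        description = plant_text(
            TextPlantSpec(
                active_verbs=meta_counts["active"],
                summary_phrases=meta_counts["summary"],
                transition_phrases=meta_counts["transition"],
                medical_terms=meta_counts["medical"],
                filler_sentences=meta_counts["filler"],
            ),
            rng=rng,
        )
        transcript = plant_text(
            TextPlantSpec(
                active_verbs=content_counts["active"],
                summary_phrases=content_counts["summary"],
                transition_phrases=content_counts["transition"],
                medical_terms=content_counts["medical"],
                filler_sentences=content_counts["filler"],
            ),
            rng=rng,
        )

        duration = float(np.exp(settings["log_duration"].draw(rng, label)))
        has_tags = rng.uniform() < (0.9 if label else 0.5)
        record = VideoRecord(
            video_id=vid,
            title=f"Managing blood sugar, part {i + 1}",
            description=description.text,
            tags=["diabetes", "patient education"] if has_tags else [],
            duration_s=round(duration, 1),
            published_days=float(round(np.exp(4.0 + 3.0 * u + rng.normal(0, 0.08)))),
            view_count=0,
            like_count=0,
            comment_count=0,
            channel_view_count=int(round(np.exp(8.0 + 8.0 * u + rng.normal(0, 0.05)))),
            channel_subscriber_count=int(round(np.exp(5.0 + 6.0 * u + rng.normal(0, 0.05)))),
            channel_video_count=max(1, int(round(np.exp(2.0 + 4.0 * u + rng.normal(0, 0.05))))),
            content_definition="SD" if rng.uniform() < (0.7 - 0.4 * u) else "HD",
        )

        conf = float(np.clip(settings["transcription_conf"].draw(rng, label), 0.0, 1.0))
        n_texts = int(rng.poisson(1.5))
        screen_texts = [
            ScreenText(
                f"slide {j + 1}",
                float(np.clip(settings["ocr_conf"].draw(rng, label), 0.0, 1.0)),
            )
            for j in range(n_texts)
        ]
        signals = VideoSignals(
            video_id=vid,
            transcript=transcript.text,
            transcription_confidence=conf,
            screen_texts=screen_texts,
            scene_count=_count(rng, settings["scene_count"], label, minimum=1),
            object_count=_count(rng, settings["object_count"], label, minimum=0),
        )
        units.append(CorpusUnit(record, signals))
        labels[vid] = label
        u_map[vid] = u
        planted[vid] = {"meta": meta_counts, "content": content_counts}

    truth = GroundTruth(
        labels=labels, u=u_map, tag_map=dict(_TAG_MAP), planted=planted, config=config
    )
    return units, truth


def generate_engagement(
    units: Sequence[CorpusUnit],
    truth: GroundTruth,
    config: Optional[SyntheticConfig] = None,
    write_back: bool = True,
) -> pd.DataFrame:
    """Draw engagement counts from the log-linear model.

    Returns a frame with, per outcome, the noise-free linear predictor,
    the noisy log value, and the rounded nonnegative count; ``write_back``
    stores the counts on the records.  Consumes its own RNG stream (offset
    from the corpus seed) so corpora with and without engagement share the
    same videos.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    names = ("view", "like", "comment")
    for unit in units:
        vid = unit.record.video_id
        label = truth.labels[vid]
        z = 2.0 * truth.u[vid] - 1.0
        row = {"video_id": vid, "label": label}
        for alpha, name in zip(config.alpha, names):
            linpred = alpha + config.tau * label + config.beta_confounder * z
            logval = linpred + (rng.normal(0, config.noise_sd) if config.noise_sd > 0 else 0.0)
            count = max(0, int(round(np.expm1(logval))))
            row[f"linpred_{name}"] = linpred
            row[f"log_{name}"] = logval
            row[f"{name}_count"] = count
        rows.append(row)
        if write_back:
            unit.record.view_count = row["view_count"]
            unit.record.like_count = row["like_count"]
            unit.record.comment_count = row["comment_count"]
    truth.tau = config.tau
    return pd.DataFrame(rows).set_index("video_id")


def extract_view_features(units: Sequence[CorpusUnit], truth: GroundTruth) -> dict:
    """Both feature views per video, extracted with the corpus's hand-tag
    map (so active-verb counts are exact); returns id -> ViewPair."""
    tagger = DictionaryTagger(truth.tag_map)
    out = {}
    for unit in units:
        meta = build_metadata_features(unit.record, tagger=tagger)
        content = build_content_features(unit.record, unit.signals, tagger=tagger)
        out[unit.record.video_id] = ViewPair(meta.as_array(), content.as_array())
    return out


# ---------------------------------------------------------------------------
# Matching-ready causal scenario

def generate_causal_units(
    n: int,
    tau: float = 2.5,
    confounding: bool = True,
    seed: int = 0,
    alpha: tuple = (8.9, 3.2, 1.6),
    beta_confounder: float = 2.0,
    noise_sd: float = 1.0,
    treatment_slope: float = 1.8,
    base_rate: float = 0.45,
) -> list[CausalUnit]:
    """Units for validating the matching estimator.

    A single latent channel-maturity confounder ``u ~ U(0,1)`` drives every
    covariate (with small independent noise), the treatment probability
    (``sigmoid(logit(base_rate) + slope*(2u-1))`` when confounding is on),
    and the outcomes.  All covariates are pre-treatment by construction.
    """
    rng = np.random.default_rng(seed)
    units = []
    base_logit = math.log(base_rate / (1 - base_rate))
    for i in range(n):
        u = float(rng.uniform())
        z = 2.0 * u - 1.0
        p_t = _sigmoid(base_logit + treatment_slope * z) if confounding else base_rate
        t = int(rng.uniform() < p_t)
        wc = max(5.0, float(round(np.exp(3.5 + 1.5 * u + rng.normal(0, 0.10)))))
        covariates = {
            "log_channel_view_count": 8.0 + 8.0 * u + float(rng.normal(0, 0.08)),
            "log_channel_subscriber_count": 5.0 + 6.0 * u + float(rng.normal(0, 0.08)),
            "log_channel_video_count": 2.0 + 4.0 * u + float(rng.normal(0, 0.08)),
            "content_definition_sd": float(rng.uniform() < (0.7 - 0.4 * u)),
            "duration_s": float(np.exp(5.0 + 1.5 * u + rng.normal(0, 0.08))),
            "description_word_count": wc,
            "description_unique_words": float(round(0.65 * wc)),
            "log_published_days": 4.0 + 3.0 * u + float(rng.normal(0, 0.08)),
        }
        outcomes = {}
        for a, name in zip(alpha, ("log_view_count", "log_like_count", "log_comment_count")):
            outcomes[name] = a + tau * t + beta_confounder * z + float(rng.normal(0, noise_sd))
        units.append(CausalUnit(f"c{i:05d}", t, covariates, outcomes))
    return units
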