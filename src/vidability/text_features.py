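"""PEMAT-mapped text and signal features for the two classifier views.

Everything here is deterministic and intentionally simple so that feature
values are exactly reproducible:

* words are maximal alphanumeric runs, optionally joined by apostrophes or
  hyphens; sentences are split on ``. ! ?`` followed by whitespace or end
  of text;
* the Automated Readability Index (ARI) and the Flesch-Kincaid grade are
  computed from the published formulas on that tokenizer (letters-only
  character counts for ARI; a vowel-group syllable heuristic for FK);
* phrase-lexicon counting is case-insensitive, at word boundaries, longest
  phrase first, non-overlapping, and never crosses a sentence boundary —
  which makes counts additive over sentence-separated concatenation;
* part-of-speech tagging is a pluggable contract (any callable mapping a
  token list to Penn-Treebank-style tags); active-voice counting itself is
  tagger-independent.

The metadata view describes how the creator frames the video (title,
description, tags, duration); the content view describes what the video
itself delivers (transcript, transcription/OCR confidences, scene and
object counts).  Each view has exactly 12 named features.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, NamedTuple, Optional, Protocol, Sequence

import numpy as np

from vidability.corpus_io import VideoRecord, VideoSignals

__all__ = [
    "MISSING",
    "tokenize_words",
    "split_sentences",
    "count_syllables",
    "readability",
    "TaggedToken",
    "ACTIVE_VERB_TAGS",
    "count_active_verbs",
    "Tagger",
    "DictionaryTagger",
    "HeuristicTagger",
    "Lexicon",
    "load_lexicon",
    "summary_lexicon",
    "transition_lexicon",
    "medical_lexicons",
    "count_lexicon_phrases",
    "count_medical_terms",
    "MetadataFeatures",
    "ContentFeatures",
    "build_metadata_features",
    "build_content_features",
]

#: Missing-value code for undefined numeric features (empty description,
#: absent confidence scores).  Downstream learners impute it explicitly.
MISSING = float("nan")

_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:['’-][A-Za-z0-9]+)*")
_SENT_SPLIT_RE = re.compile(r"[.!?]+(?:\s+|$)")


def tokenize_words(text: str, lowercase: bool = False) -> list[str]:
    """Maximal alphanumeric(+apostrophe/hyphen) runs."""
    tokens = _WORD_RE.findall(text)
    return [t.lower() for t in tokens] if lowercase else tokens


def split_sentences(text: str) -> list[str]:
    """Segments between ``. ! ?`` terminators; only segments with words count."""
    parts = _SENT_SPLIT_RE.split(text)
    return [p for p in parts if _WORD_RE.search(p)]


_VOWELS = set("aeiouy")


def count_syllables(word: str) -> int:
    """Vowel-group heuristic: consecutive vowels are one syllable, a silent
    final "e" is dropped (unless the word ends in a consonant + "le"), and
    every word has at least one syllable.  Approximate by design.
    """
    w = word.lower()
    w = re.sub(r"[^a-z]", "", w)
    if not w:
        return 1
    if w.endswith("e") and not w.endswith("le"):
        w = w[:-1]
    groups = len(re.findall(r"[aeiouy]+", w))
    return max(1, groups)


def readability(text: str, index: str = "ARI") -> float:
    """Readability score of ``text`` under the named index.

    ARI      = 4.71*(letters/words) + 0.5*(words/sentences) - 21.43
    FK_grade = 0.39*(words/sentences) + 11.8*(syllables/words) - 15.59
    """
    words = tokenize_words(text)
    if not words:
        raise ValueError("readability is undefined for text with zero words")
    n_words = len(words)
    n_sentences = max(1, len(split_sentences(text)))
    if index == "ARI":
        letters = sum(1 for c in text if c.isalpha())
        return 4.71 * (letters / n_words) + 0.5 * (n_words / n_sentences) - 21.43
    if index == "FK_grade":
        syllables = sum(count_syllables(w) for w in words)
        return 0.39 * (n_words / n_sentences) + 11.8 * (syllables / n_words) - 15.59
    raise ValueError(f"unknown readability index {index!r} (expected 'ARI' or 'FK_grade')")


# ---------------------------------------------------------------------------
# Part-of-speech tagging and active-voice counting

class TaggedToken(NamedTuple):
    token: str
    pos_tag: str


#: Verb tags counted as active voice: base form (VB), past tense (VBD),
#: gerund/present participle (VBG), non-3rd-person present (VBP) and
#: 3rd-person-singular present (VBZ).  Past participles (VBN) — the verb
#: form that realizes the passive — are excluded.
ACTIVE_VERB_TAGS = frozenset({"VB", "VBD", "VBG", "VBP", "VBZ"})


def count_active_verbs(tokens: Iterable[TaggedToken]) -> int:
    return sum(1 for t in tokens if t.pos_tag in ACTIVE_VERB_TAGS)


class Tagger(Protocol):
    """Tagging backend contract: tokens in, Penn-Treebank-style tags out."""

    def tag(self, tokens: Sequence[str]) -> list[TaggedToken]:
        ...


class DictionaryTagger:
    """Tag by case-insensitive lookup; unknown tokens get ``default``."""

    def __init__(self, mapping: dict, default: str = "NN"):
        self.mapping = {k.lower(): v for k, v in mapping.items()}
        self.default = default

    def tag(self, tokens: Sequence[str]) -> list[TaggedToken]:
        return [TaggedToken(t, self.mapping.get(t.lower(), self.default)) for t in tokens]


_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT",
    "i": "PRP", "you": "PRP", "he": "PRP", "she": "PRP", "it": "PRP",
    "we": "PRP", "they": "PRP",
    "in": "IN", "on": "IN", "at": "IN", "of": "IN", "for": "IN",
    "with": "IN", "from": "IN", "by": "IN", "about": "IN", "to": "TO",
    "and": "CC", "or": "CC", "but": "CC",
    "is": "VBZ", "are": "VBP", "am": "VBP", "was": "VBD", "were": "VBD",
    "be": "VB", "been": "VBN", "being": "VBG",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "does": "VBZ", "do": "VBP", "did": "VBD",
}

_VERB_STEMS = {
    "check", "explain", "describe", "show", "review", "present", "discuss",
    "ask", "write", "walk", "take", "make", "use", "help", "learn",
    "manage", "monitor", "eat", "test", "measure", "start", "stop",
    "keep", "need", "want", "tell", "give", "get", "go", "see", "watch",
    "talk", "read", "cover", "teach",
}


class HeuristicTagger:
    """Small rule-based default tagger (closed-class lexicon, a common-verb
    stem list, and suffix rules).  Adequate for feature extraction; tests of
    active-voice counting use hand-tagged tokens instead.
    """

    def tag(self, tokens: Sequence[str]) -> list[TaggedToken]:
        out = []
        for tok in tokens:
            low = tok.lower()
            if low in _CLOSED_CLASS:
                tag = _CLOSED_CLASS[low]
            elif low.isdigit():
                tag = "CD"
            elif low in _VERB_STEMS:
                tag = "VB"
            elif low.endswith("ing") and low[:-3] in _VERB_STEMS:
                tag = "VBG"
            elif low.endswith("ed") and (low[:-2] in _VERB_STEMS or low[:-1] in _VERB_STEMS):
                tag = "VBD"
            elif low.endswith("s") and low[:-1] in _VERB_STEMS:
                tag = "VBZ"
            elif low.endswith("es") and low[:-2] in _VERB_STEMS:
                tag = "VBZ"
            else:
                tag = "NN"
            out.append(TaggedToken(tok, tag))
        return out


DEFAULT_TAGGER = HeuristicTagger()


# ---------------------------------------------------------------------------
# Phrase lexicons

@dataclass(frozen=True)
class Lexicon:
    """A named set of lowercase phrases (each one or more words)."""

    name: str
    phrases: frozenset
    category: Optional[str] = None

    def __post_init__(self):
        if not self.phrases:
            raise ValueError(f"lexicon {self.name!r} is empty")
        if any(not p or not p.strip() for p in self.phrases):
            raise ValueError(f"lexicon {self.name!r} contains an empty phrase")

    def token_tuples(self) -> frozenset:
        return _token_tuples(self.phrases)


@lru_cache(maxsize=128)
def _token_tuples(phrases: frozenset) -> frozenset:
    return frozenset(tuple(tokenize_words(p, lowercase=True)) for p in phrases)


def _parse_lexicon_lines(lines: Iterable[str], fallback_name: str) -> Lexicon:
    name, category = fallback_name, None
    phrases = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            header = line.lstrip("#").strip()
            if header.lower().startswith("lexicon:"):
                name = header.split(":", 1)[1].strip()
            elif header.lower().startswith("category:"):
                category = header.split(":", 1)[1].strip()
            continue
        phrases.append(line.lower())
    return Lexicon(name=name, phrases=frozenset(phrases), category=category)


def load_lexicon(path) -> Lexicon:
    """Load a plain-text lexicon (one phrase per line, ``#``-headers for
    name and category)."""
    with open(path, encoding="utf-8") as fh:
        return _parse_lexicon_lines(fh, fallback_name=str(path))


@lru_cache(maxsize=None)
def _load_packaged(filename: str) -> Lexicon:
    ref = resources.files("vidability").joinpath("data/lexicons").joinpath(filename)
    return _parse_lexicon_lines(ref.read_text(encoding="utf-8").splitlines(), filename)


_MEDICAL_FILES = (
    "medical_body_part.txt",
    "medical_chemicals_drugs.txt",
    "medical_devices.txt",
    "medical_events.txt",
    "medical_professionals.txt",
    "medical_procedures.txt",
)

MEDICAL_CATEGORIES = (
    "body_part",
    "chemicals_drugs",
    "medical_devices",
    "medical_events",
    "medical_professionals",
    "medical_procedures",
)


def summary_lexicon() -> Lexicon:
    """Packaged summary/conclusion cue phrases."""
    return _load_packaged("summary.txt")


def transition_lexicon() -> Lexicon:
    """Packaged transition cue words and phrases."""
    return _load_packaged("transition.txt")


def medical_lexicons() -> list[Lexicon]:
    """Packaged starter term lists for the six medical-term categories
    (body parts, chemicals/drugs, devices, events, professionals,
    procedures).  Deliberately small; extend with :func:`load_lexicon`.
    """
    return [_load_packaged(f) for f in _MEDICAL_FILES]


def _match_phrases(tokens: Sequence[str], table: dict) -> list:
    """Greedy longest-first non-overlapping matches within one token list.

    ``table`` maps phrase token-tuples to an arbitrary payload; returns the
    payloads of the matches in order.
    """
    if not table:
        return []
    max_len = max(len(k) for k in table)
    out = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            key = tuple(tokens[i : i + length])
            if key in table:
                hit = (length, table[key])
                break
        if hit is None:
            i += 1
        else:
            out.append(hit[1])
            i += hit[0]
    return out


def _sentence_token_lists(text: str) -> list[list[str]]:
    return [tokenize_words(s, lowercase=True) for s in split_sentences(text)]


def count_lexicon_phrases(text: str, lexicon: Lexicon) -> int:
    """Case-insensitive, word-boundary, longest-first non-overlapping count
    of lexicon phrases; matches never span a sentence boundary."""
    table = {k: True for k in lexicon.token_tuples()}
    return sum(len(_match_phrases(toks, table)) for toks in _sentence_token_lists(text))


def count_medical_terms(text: str, lexicons: Optional[Sequence[Lexicon]] = None):
    """Dictionary matcher over the medical category lexicons.

    Returns ``(total, per_category)``; per-category counts sum to the
    total.  The same longest-first non-overlapping rule applies across the
    merged dictionary, so "insulin pen" is counted once as a device, not as
    a drug plus a stray token.  Any recognizer producing per-category
    counts can replace this (the feature builders only consume the counts).
    """
    if lexicons is None:
        lexicons = medical_lexicons()
    table: dict = {}
    categories = []
    for lex in lexicons:
        cat = lex.category or lex.name
        if cat not in categories:
            categories.append(cat)
        for key in lex.token_tuples():
            table.setdefault(key, cat)  # first lexicon wins on duplicates
    per_category = {cat: 0 for cat in categories}
    for toks in _sentence_token_lists(text):
        for cat in _match_phrases(toks, table):
            per_category[cat] += 1
    return sum(per_category.values()), per_category


# ---------------------------------------------------------------------------
# Feature vectors (12 named slots per view)

@dataclass(frozen=True)
class MetadataFeatures:
    """The 12 metadata-view features, in canonical order (see FIELDS)."""

    has_title: int
    has_description: int
    has_tags: int
    description_readability: float
    active_word_count: int
    summary_word_count: int
    transition_word_count: int
    video_duration: float
    description_word_count: int
    sentence_count: int
    description_unique_words: int
    description_medical_term_count: int

    FIELDS = (
        "has_title",
        "has_description",
        "has_tags",
        "description_readability",
        "active_word_count",
        "summary_word_count",
        "transition_word_count",
        "video_duration",
        "description_word_count",
        "sentence_count",
        "description_unique_words",
        "description_medical_term_count",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}


@dataclass(frozen=True)
class ContentFeatures:
    """The 12 content-view features, in canonical order (see FIELDS)."""

    narrative_readability: float
    active_word_count: int
    summary_word_count: int
    transition_word_count: int
    video_transcription_confidence: float
    text_detection_confidence: float
    scene_count: int
    transcript_word_count: int
    transcript_unique_word: int
    transcript_sentence_count: int
    transcript_medical_term: int
    video_object: int

    FIELDS = (
        "narrative_readability",
        "active_word_count",
        "summary_word_count",
        "transition_word_count",
        "video_transcription_confidence",
        "text_detection_confidence",
        "scene_count",
        "transcript_word_count",
        "transcript_unique_word",
        "transcript_sentence_count",
        "transcript_medical_term",
        "video_object",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}


def _text_counts(text, summary_lex, transition_lex, med_lexs, tagger):
    words = tokenize_words(text)
    if not words:
        return dict(
            readability=MISSING, active=0, summary=0, transition=0,
            words=0, sentences=0, unique=0, medical=0,
        )
    return dict(
        readability=None,  # caller computes with its chosen index
        active=count_active_verbs(tagger.tag(words)),
        summary=count_lexicon_phrases(text, summary_lex),
        transition=count_lexicon_phrases(text, transition_lex),
        words=len(words),
        sentences=len(split_sentences(text)),
        unique=len({w.lower() for w in words}),
        medical=count_medical_terms(text, med_lexs)[0],
    )


def build_metadata_features(
    record: VideoRecord,
    *,
    summary_lex: Optional[Lexicon] = None,
    transition_lex: Optional[Lexicon] = None,
    medical_lexs: Optional[Sequence[Lexicon]] = None,
    tagger: Optional[Tagger] = None,
    readability_index: str = "ARI",
) -> MetadataFeatures:
    """Metadata-view features from title/description/tags/duration.

    An empty description yields zero counts and the missing-value code for
    readability (the purpose-evident flags treat empty text as absent).
    """
    summary_lex = summary_lex or summary_lexicon()
    transition_lex = transition_lex or transition_lexicon()
    medical_lexs = medical_lexs if medical_lexs is not None else medical_lexicons()
    tagger = tagger or DEFAULT_TAGGER

    c = _text_counts(record.description, summary_lex, transition_lex, medical_lexs, tagger)
    score = MISSING if c["words"] == 0 else readability(record.description, readability_index)
    return MetadataFeatures(
        has_title=int(bool(record.title.strip())),
        has_description=int(c["words"] > 0),
        has_tags=int(any(t.strip() for t in record.tags)),
        description_readability=score,
        active_word_count=c["active"],
        summary_word_count=c["summary"],
        transition_word_count=c["transition"],
        video_duration=float(record.duration_s),
        description_word_count=c["words"],
        sentence_count=c["sentences"],
        description_unique_words=c["unique"],
        description_medical_term_count=c["medical"],
    )


def build_content_features(
    record: VideoRecord,
    signals: Optional[VideoSignals],
    *,
    summary_lex: Optional[Lexicon] = None,
    transition_lex: Optional[Lexicon] = None,
    medical_lexs: Optional[Sequence[Lexicon]] = None,
    tagger: Optional[Tagger] = None,
    readability_index: str = "ARI",
) -> ContentFeatures:
    """Content-view features from the transcript and content signals.

    Raises if ``signals`` is absent: units without content signals cannot
    supply this view and should be excluded from two-view analyses.
    """
    if signals is None:
        raise ValueError(
            f"video {record.video_id!r} has no content signals; "
            "exclude it from two-view analyses"
        )
    summary_lex = summary_lex or summary_lexicon()
    transition_lex = transition_lex or transition_lexicon()
    medical_lexs = medical_lexs if medical_lexs is not None else medical_lexicons()
    tagger = tagger or DEFAULT_TAGGER

    c = _text_counts(signals.transcript, summary_lex, transition_lex, medical_lexs, tagger)
    score = MISSING if c["words"] == 0 else readability(signals.transcript, readability_index)
    if signals.screen_texts:
        ocr_conf = float(np.mean([st.confidence for st in signals.screen_texts]))
    else:
        ocr_conf = MISSING
    asr_conf = (
        MISSING
        if signals.transcription_confidence is None
        else float(signals.transcription_confidence)
    )
    return ContentFeatures(
        narrative_readability=score,
        active_word_count=c["active"],
        summary_word_count=c["summary"],
        transition_word_count=c["transition"],
        video_transcription_confidence=asr_conf,
        text_detection_confidence=ocr_conf,
        scene_count=signals.scene_count,
        transcript_word_count=c["words"],
        transcript_unique_word=c["unique"],
        transcript_sentence_count=c["sentences"],
        transcript_medical_term=c["medical"],
        video_object=signals.object_count,
    )


def features_to_frame(features: dict, cls) -> "pd.DataFrame":
    """Feature mapping (video_id -> features) to a DataFrame keyed by id."""
    import pandas as pd

    rows = {vid: f.as_dict() for vid, f in features.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(cls.FIELDS))
    frame.index.name = "video_id"
    return frame
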