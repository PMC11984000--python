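"""Corpus artifacts: video records, content signals, annotations.

Video metadata and per-video content signals are stored as JSON Lines (one
object per line, keys equal to the dataclass field names); expert item
annotations as CSV.  A missing optional text field is normalized to empty
text and missing tags to the empty list, so "absent" and "empty" coincide
by design; the derived purpose-evident flags treat empty as absent.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "ValidationError",
    "VideoRecord",
    "VideoSignals",
    "ScreenText",
    "CorpusUnit",
    "read_corpus",
    "write_corpus",
    "read_annotations",
    "write_annotations",
]

CONTENT_DEFINITIONS = ("SD", "HD")


class ValidationError(ValueError):
    """A corpus artifact violates its schema (message names line and field)."""


class ScreenText(NamedTuple):
    """One on-screen text detection with its recognition confidence."""

    text: str
    confidence: float


@dataclass
class VideoRecord:
    """Creator-supplied metadata, channel statistics, and engagement counts.

    ``published_days`` is the age of the video (days since publication) at
    collection time; it is stored, never derived from the clock, so that
    runs are reproducible.
    """

    video_id: str
    title: str = ""
    description: str = ""
    tags: list = field(default_factory=list)
    duration_s: float = 0.0
    published_days: float = 0.0
    view_count: int = 0
    like_count: int = 0
    comment_count: int = 0
    channel_view_count: int = 0
    channel_subscriber_count: int = 0
    channel_video_count: int = 0
    content_definition: str = "HD"

    _COUNT_FIELDS = (
        "view_count",
        "like_count",
        "comment_count",
        "channel_view_count",
        "channel_subscriber_count",
        "channel_video_count",
    )

    def validate(self) -> None:
        if not self.video_id:
            raise ValidationError("video_id: must be nonempty")
        for name in self._COUNT_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValidationError(f"{name}: must be a nonnegative integer, got {value!r}")
        for name in ("duration_s", "published_days"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or value < 0:
                raise ValidationError(f"{name}: must be a nonnegative number, got {value!r}")
        if self.content_definition not in CONTENT_DEFINITIONS:
            raise ValidationError(
                f"content_definition: must be one of {CONTENT_DEFINITIONS}, got {self.content_definition!r}"
            )
        if not isinstance(self.tags, list) or any(not isinstance(t, str) for t in self.tags):
            raise ValidationError("tags: must be a list of strings")


@dataclass
class VideoSignals:
    """Precomputed content-analysis outputs for one video.

    These stand in for the outputs of an automated video-intelligence stage:
    speech transcript with its transcription confidence, on-screen text
    detections with per-detection OCR confidences, and scene/object counts.
    The channels are independent: an empty transcript does not constrain the
    scene count.
    """

    video_id: str
    transcript: str = ""
    transcription_confidence: Optional[float] = None
    screen_texts: list = field(default_factory=list)  # list[ScreenText]
    scene_count: int = 0
    object_count: int = 0

    def validate(self) -> None:
        if not self.video_id:
            raise ValidationError("video_id: must be nonempty")
        if self.transcription_confidence is not None and not (
            0.0 <= self.transcription_confidence <= 1.0
        ):
            raise ValidationError(
                f"transcription_confidence: must lie in [0,1], got {self.transcription_confidence!r}"
            )
        for st in self.screen_texts:
            if not (0.0 <= st.confidence <= 1.0):
                raise ValidationError(
                    f"screen_texts: confidence must lie in [0,1], got {st.confidence!r}"
                )
        for name in ("scene_count", "object_count"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValidationError(f"{name}: must be a nonnegative integer, got {value!r}")


class CorpusUnit(NamedTuple):
    """One video with its (possibly absent) content signals."""

    record: VideoRecord
    signals: Optional[VideoSignals]


def _record_from_obj(obj: dict, line_no: int) -> VideoRecord:
    known = {f for f in VideoRecord.__dataclass_fields__}
    unknown = set(obj) - known
    if unknown:
        raise ValidationError(f"line {line_no}: unknown field(s) {sorted(unknown)}")
    if "video_id" not in obj:
        raise ValidationError(f"line {line_no}: video_id: missing required field")
    try:
        rec = VideoRecord(**obj)
        rec.validate()
    except ValidationError as exc:
        raise ValidationError(f"line {line_no}: {exc}") from None
    except TypeError as exc:
        raise ValidationError(f"line {line_no}: {exc}") from None
    return rec


def _signals_from_obj(obj: dict, line_no: int) -> VideoSignals:
    obj = dict(obj)
    if "video_id" not in obj:
        raise ValidationError(f"line {line_no}: video_id: missing required field")
    raw = obj.pop("screen_texts", [])
    try:
        texts = [ScreenText(str(t), float(c)) for t, c in raw]
    except (TypeError, ValueError):
        raise ValidationError(
            f"line {line_no}: screen_texts: expected a list of [text, confidence] pairs"
        ) from None
    try:
        sig = VideoSignals(screen_texts=texts, **obj)
        sig.validate()
    except ValidationError as exc:
        raise ValidationError(f"line {line_no}: {exc}") from None
    except TypeError as exc:
        raise ValidationError(f"line {line_no}: {exc}") from None
    return sig


def _iter_jsonl(path: Path):
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"line {line_no}: invalid JSON ({exc.msg})") from None
            if not isinstance(obj, dict):
                raise ValidationError(f"line {line_no}: expected a JSON object")
            yield line_no, obj


def read_corpus(records_path, signals_path=None) -> list[CorpusUnit]:
    """Read a corpus, joining content signals to records by ``video_id``.

    Input order is preserved; units whose video has no signals row carry
    ``signals=None``.  Duplicate ids in either file are an error.
    """
    records_path = Path(records_path)
    records: list[VideoRecord] = []
    seen: set[str] = set()
    for line_no, obj in _iter_jsonl(records_path):
        rec = _record_from_obj(obj, line_no)
        if rec.video_id in seen:
            raise ValidationError(f"line {line_no}: duplicate video_id {rec.video_id!r}")
        seen.add(rec.video_id)
        records.append(rec)

    signals: dict[str, VideoSignals] = {}
    if signals_path is not None:
        for line_no, obj in _iter_jsonl(Path(signals_path)):
            sig = _signals_from_obj(obj, line_no)
            if sig.video_id in signals:
                raise ValidationError(f"line {line_no}: duplicate video_id {sig.video_id!r}")
            signals[sig.video_id] = sig

    return [CorpusUnit(rec, signals.get(rec.video_id)) for rec in records]


def write_corpus(units: Sequence[CorpusUnit], records_path, signals_path=None) -> None:
    """Write a corpus back to JSON Lines; round-trips with :func:`read_corpus`."""
    ids = [u.record.video_id for u in units]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate video_id {dup[0]!r}")
    for u in units:
        u.record.validate()
        if u.signals is not None:
            u.signals.validate()

    with open(records_path, "w", encoding="utf-8") as fh:
        for u in units:
            fh.write(json.dumps(asdict(u.record), sort_keys=False) + "\n")

    if signals_path is not None:
        with open(signals_path, "w", encoding="utf-8") as fh:
            for u in units:
                if u.signals is None:
                    continue
                obj = asdict(u.signals)
                obj["screen_texts"] = [[t, c] for t, c in u.signals.screen_texts]
                fh.write(json.dumps(obj) + "\n")


# ---------------------------------------------------------------------------
# Annotation CSV (header: video_id,item_01..item_12 with 0/1/NA tokens)

def read_annotations(path) -> list:
    """Read expert item annotations; returns :class:`vidability.pemat.PEMATAssessment` list."""
    from vidability.pemat import N_ITEMS, PEMATAssessment

    expected = ["video_id"] + [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != expected:
            raise ValidationError(f"line 1: expected header {','.join(expected)}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected):
                raise ValidationError(f"line {line_no}: expected {len(expected)} columns")
            scores = []
            for col, token in zip(expected[1:], row[1:]):
                token = token.strip()
                if token == "NA":
                    scores.append(None)
                elif token in ("0", "1"):
                    scores.append(int(token))
                else:
                    raise ValidationError(f"line {line_no}: {col}: expected 0, 1 or NA, got {token!r}")
            try:
                assessment = PEMATAssessment(video_id=row[0], item_scores=tuple(scores))
            except ValueError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from None
            out.append(assessment)
    return out


def write_annotations(assessments, path) -> None:
    from vidability.pemat import N_ITEMS

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["video_id"] + [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)])
        for a in assessments:
            writer.writerow(
                [a.video_id] + ["NA" if s is None else str(s) for s in a.item_scores]
            )
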