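"""PEMAT understandability assessments for audio/visual materials.

The Patient Education Materials Assessment Tool (PEMAT, AHRQ) rates a
material on 12 understandability items grouped under content, word choice
and style, organization, and layout and design.  Each item is scored
1 (agree) or 0 (disagree); 7 of the items may instead be marked not
applicable (for example, a video with no on-screen tables cannot be rated
on table design).  The understandability score of a material is

    score = 100 * (# items scored 1) / (# applicable items),

and a material is labeled *high* understandability when the score strictly
exceeds 50%.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "PEMATItem",
    "ITEMS",
    "N_ITEMS",
    "PEMATAssessment",
    "UnderstandabilityResult",
    "AnnotationSummary",
    "understandability_score",
    "summarize_annotations",
    "REFERENCE_MARGINALS",
    "REFERENCE_N",
    "REFERENCE_OVERALL",
    "assessments_from_marginals",
    "round_pct",
]


class PEMATItem(NamedTuple):
    code: str
    aspect: str
    text: str
    na_allowed: bool


#: The 12 audio/visual understandability items.  Five items are strictly
#: 0/1; seven admit a not-applicable answer.
ITEMS: tuple[PEMATItem, ...] = (
    PEMATItem("purpose_evident", "content", "The material makes its purpose completely evident.", False),
    PEMATItem("everyday_language", "word choice and style", "The material uses common, everyday language.", False),
    PEMATItem("medical_terms_defined", "word choice and style", "Medical terms are used only to familiarize the audience with the terms. When used, medical terms are defined.", False),
    PEMATItem("active_voice", "word choice and style", "The material uses the active voice.", False),
    PEMATItem("chunked_sections", "organization", "The material breaks or “chunks” information into short sections.", True),
    PEMATItem("informative_headers", "organization", "The material’s sections have informative headers.", True),
    PEMATItem("logical_sequence", "organization", "The material presents information in a logical sequence.", False),
    PEMATItem("provides_summary", "organization", "The material provides a summary.", True),
    PEMATItem("text_easy_to_read", "layout and design", "The text on the screen is easy to read.", True),
    PEMATItem("words_clear", "layout and design", "The material allows the user to hear the words clearly.", True),
    PEMATItem("clear_illustrations", "layout and design", "The material uses illustrations and photographs that are clear and uncluttered.", True),
    PEMATItem("simple_tables", "layout and design", "The material uses simple tables with short and clear row and column headings.", True),
)

N_ITEMS = len(ITEMS)
NA_ALLOWED = tuple(item.na_allowed for item in ITEMS)


def round_pct(numerator: float, denominator: float, places: int = 1) -> float:
    """Exact percentage, rounded half-up to ``places`` decimals for reporting."""
    q = Decimal(1).scaleb(-places)
    return float(
        (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class PEMATAssessment:
    """One expert's 12-item rating of one video (``None`` = not applicable)."""

    video_id: str
    item_scores: tuple  # 12 entries in {0, 1, None}

    def __post_init__(self):
        if len(self.item_scores) != N_ITEMS:
            raise ValueError(f"item_scores: expected {N_ITEMS} entries, got {len(self.item_scores)}")
        for idx, (score, item) in enumerate(zip(self.item_scores, ITEMS), start=1):
            if score is None:
                if not item.na_allowed:
                    raise ValueError(f"item_{idx:02d} ({item.code}): N/A is not permitted for this item")
            elif score not in (0, 1):
                raise ValueError(f"item_{idx:02d} ({item.code}): expected 0, 1 or NA, got {score!r}")
        if all(s is None for s in self.item_scores):
            raise ValueError("all items are N/A; the score denominator is undefined")


@dataclass(frozen=True)
class UnderstandabilityResult:
    score_pct: float  # in [0, 100]
    label: str  # "low" or "high"
    n_applicable: int


def understandability_score(assessment: PEMATAssessment) -> UnderstandabilityResult:
    """Score = 100 * agreed / applicable; label *high* iff score > 50 (strict)."""
    applicable = [s for s in assessment.item_scores if s is not None]
    n_applicable = len(applicable)
    score = 100.0 * sum(applicable) / n_applicable
    return UnderstandabilityResult(
        score_pct=score,
        label="high" if score > 50.0 else "low",
        n_applicable=n_applicable,
    )


@dataclass(frozen=True)
class AnnotationSummary:
    """Item-level 0/1/NA counts and the derived overall low/high split."""

    n: int
    item_counts: tuple  # per item: (count0, count1, countNA)
    overall_low: int
    overall_high: int

    def item_pct(self, item_index: int) -> tuple[float, float, float]:
        c0, c1, cna = self.item_counts[item_index]
        return (round_pct(c0, self.n), round_pct(c1, self.n), round_pct(cna, self.n))

    @property
    def overall_low_pct(self) -> float:
        return round_pct(self.overall_low, self.n)

    @property
    def overall_high_pct(self) -> float:
        return round_pct(self.overall_high, self.n)

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per item plus an overall row."""
        rows = []
        for idx, item in enumerate(ITEMS):
            c0, c1, cna = self.item_counts[idx]
            p0, p1, pna = self.item_pct(idx)
            rows.append((item.text, c0, p0, c1, p1, cna, pna))
        rows.append(
            (
                "Understandability",
                self.overall_low,
                self.overall_low_pct,
                self.overall_high,
                self.overall_high_pct,
                0,
                0.0,
            )
        )
        return pd.DataFrame(
            rows,
            columns=["variable", "n_0", "pct_0", "n_1", "pct_1", "n_na", "pct_na"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "n": self.n,
            "items": {
                ITEMS[i].code: {
                    "n_0": self.item_counts[i][0],
                    "n_1": self.item_counts[i][1],
                    "n_na": self.item_counts[i][2],
                }
                for i in range(N_ITEMS)
            },
            "overall": {
                "low": self.overall_low,
                "high": self.overall_high,
                "low_pct": self.overall_low_pct,
                "high_pct": self.overall_high_pct,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def summarize_annotations(assessments: Sequence[PEMATAssessment]) -> AnnotationSummary:
    """Exact item-level counts and the derived overall understandability split."""
    if not assessments:
        raise ValueError("cannot summarize an empty list of assessments")
    counts = [[0, 0, 0] for _ in range(N_ITEMS)]
    low = high = 0
    for a in assessments:
        for idx, score in enumerate(a.item_scores):
            counts[idx][2 if score is None else score] += 1
        if understandability_score(a).label == "high":
            high += 1
        else:
            low += 1
    return AnnotationSummary(
        n=len(assessments),
        item_counts=tuple((c0, c1, cna) for c0, c1, cna in counts),
        overall_low=low,
        overall_high=high,
    )


# ---------------------------------------------------------------------------
# Reference annotation campaign (700 diabetes patient-education videos)

#: Item-level marginal counts (n0, n1, nNA) from an expert annotation
#: campaign of 700 diabetes education videos, in ITEMS order.
REFERENCE_MARGINALS: tuple[tuple[int, int, int], ...] = (
    (175, 525, 0),
    (183, 517, 0),
    (241, 459, 0),
    (174, 526, 0),
    (548, 143, 9),
    (601, 90, 9),
    (164, 536, 0),
    (458, 233, 9),
    (137, 294, 269),
    (97, 539, 64),
    (111, 338, 251),
    (192, 57, 451),
)

REFERENCE_N = 700
#: Overall (low, high) understandability split of the same campaign.
REFERENCE_OVERALL = (315, 385)


def assessments_from_marginals(
    marginals: Sequence[tuple[int, int, int]] = REFERENCE_MARGINALS,
    n: int = REFERENCE_N,
    overall: Optional[tuple[int, int]] = REFERENCE_OVERALL,
    id_prefix: str = "ref",
) -> list[PEMATAssessment]:
    """Construct ``n`` assessments matching per-item marginal counts.

    Only the marginals are constrained; within a row, items are filled by a
    deterministic packing followed by marginal-preserving swaps so that,
    when ``overall`` is given, exactly ``overall[1]`` rows derive a *high*
    label under the strict >50% rule.  Raises if the targets cannot be
    reconciled.
    """
    if len(marginals) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} marginal triples")
    for idx, (c0, c1, cna) in enumerate(marginals):
        if c0 + c1 + cna != n:
            raise ValueError(f"item {idx + 1}: counts sum to {c0 + c1 + cna}, expected {n}")
        if cna and not NA_ALLOWED[idx]:
            raise ValueError(f"item {idx + 1}: N/A count for a strict 0/1 item")

    n_high = overall[1] if overall is not None else None

    # Initial packing: per item, rows 0..c1-1 get 1, the next cna rows get
    # N/A, the rest 0.  High-target rows come first, so agreement lands on
    # them and N/A cushions the boundary.
    grid = [[0] * N_ITEMS for _ in range(n)]
    for j, (c0, c1, cna) in enumerate(marginals):
        for r in range(n):
            if r < c1:
                grid[r][j] = 1
            elif r < c1 + cna:
                grid[r][j] = None
            else:
                grid[r][j] = 0

    if n_high is not None:
        targets = [1 if r < n_high else 0 for r in range(n)]

        def is_high(row):
            applicable = [s for s in row if s is not None]
            return sum(applicable) * 2 > len(applicable)

        def failing():
            return [r for r in range(n) if is_high(grid[r]) != targets[r]]

        # Marginal-preserving repair: swap one item's value between two rows.
        # A row labeled high but targeted low sheds a 1 to a row that can
        # absorb it (stays on-target after the swap); the mirror case gains
        # a 1 the same way.  Each swap strictly reduces the number of
        # off-target rows or keeps it while draining overloaded rows, and
        # the loop is bounded.
        for _ in range(8 * n):
            bad = failing()
            if not bad:
                break
            r = bad[0]
            fixed = False
            if targets[r] == 0:  # row is high, must shed a 1
                for j in range(N_ITEMS):
                    if grid[r][j] != 1:
                        continue
                    for d in range(n):
                        if d == r or grid[d][j] != 0:
                            continue
                        grid[r][j], grid[d][j] = 0, 1
                        if is_high(grid[d]) == targets[d]:
                            fixed = True
                            break
                        grid[r][j], grid[d][j] = 1, 0  # undo; donor went off-target
                    if fixed:
                        break
            else:  # row is low, must gain a 1
                for j in range(N_ITEMS):
                    if grid[r][j] != 0:
                        continue
                    for d in range(n):
                        if d == r or grid[d][j] != 1:
                            continue
                        grid[r][j], grid[d][j] = 1, 0
                        if is_high(grid[d]) == targets[d]:
                            fixed = True
                            break
                        grid[r][j], grid[d][j] = 0, 1
                    if fixed:
                        break
            if not fixed:
                raise ValueError("could not reconcile marginals with the overall split")
        else:
            raise ValueError("marginal repair did not converge")

    assessments = [
        PEMATAssessment(video_id=f"{id_prefix}{r:04d}", item_scores=tuple(grid[r]))
        for r in range(n)
    ]

    # Verify the construction before handing it out.
    summary = summarize_annotations(assessments)
    if summary.item_counts != tuple(tuple(m) for m in marginals):
        raise AssertionError("constructed assessments do not match the requested marginals")
    if n_high is not None and (summary.overall_low, summary.overall_high) != tuple(overall):
        raise AssertionError("constructed assessments do not match the requested overall split")
    return assessments
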