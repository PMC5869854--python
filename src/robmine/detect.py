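"""The detector: boolean risk-of-bias calls with auditable evidence.

Text is normalized (lowercased, whitespace collapsed, line-break hyphenation
joined) before matching.  A document is called positive for an item iff at
least one inclusion pattern matches at a position not overlapped by any
exclusion-pattern match; every surviving match is returned as evidence with
its character span and a context snippet, so a call can always be traced back
to the text that produced it.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

from .corpus import ITEMS, Corpus, Document
from .patterns import CompiledPatternSet, PatternSet

SNIPPET_CONTEXT = 60  # characters of context kept either side of a match


@dataclasses.dataclass(frozen=True)
class MatchEvidence:
    """One surviving inclusion match, located in the normalized text."""

    pattern_id: str
    start: int  # 0-based, inclusive, in normalized text
    end: int    # exclusive
    snippet: str


@dataclasses.dataclass(frozen=True)
class RobCall:
    """Boolean call for one document and one item; true iff evidence exists."""

    doc_id: str
    item: str
    call: bool
    evidence: tuple[MatchEvidence, ...] = ()

    def __post_init__(self) -> None:
        assert self.call == bool(self.evidence)


def normalize_text(text: str) -> tuple[str, list[int]]:
    """Lowercase, de-hyphenate line breaks, collapse whitespace.

    Returns the normalized text and an offset map: ``offsets[i]`` is the index
    in the original text of the character that produced normalized position
    ``i``, so evidence spans can be projected back onto the raw document.
    """
    norm: list[str] = []
    offsets: list[int] = []
    i, n = 0, len(text)
    pending_space = False  # a whitespace run awaiting a following token
    pending_at = 0
    while i < n:
        ch = text[i]
        # join words hyphenated across a line break: "rando-\nmization"
        if ch == "-" and text[i + 1 : i + 2] == "\n":
            i += 2
            continue
        if ch == "-" and text[i + 1 : i + 3] == "\r\n":
            i += 3
            continue
        if ch.isspace():
            pending_space = True
            pending_at = i
            i += 1
            continue
        if pending_space and norm:
            norm.append(" ")
            offsets.append(pending_at)
        pending_space = False
        for low in ch.lower():
            norm.append(low)
            offsets.append(i)
        i += 1
    return "".join(norm), offsets


def _spans_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def detect(document: Document, pattern_set: PatternSet | CompiledPatternSet) -> RobCall:
    """Apply one item's pattern set to a document.

    Exclusion semantics are span-overlap suppression: an inclusion match whose
    span intersects any exclusion match is discarded.  Evidence is returned in
    ascending start order.
    """
    compiled = pattern_set.compiled() if isinstance(pattern_set, PatternSet) else pattern_set
    norm, _ = normalize_text(document.text)

    excl_spans: list[tuple[int, int]] = []
    for _, regex in compiled.exclude:
        for m in regex.finditer(norm):
            excl_spans.append(m.span())

    evidence: list[MatchEvidence] = []
    for pid, regex in compiled.include:
        for m in regex.finditer(norm):
            s, e = m.span()
            if s == e:
                continue  # zero-width matches carry no evidence
            if any(_spans_overlap(s, e, xs, xe) for xs, xe in excl_spans):
                continue
            snippet = norm[max(0, s - SNIPPET_CONTEXT) : e + SNIPPET_CONTEXT]
            evidence.append(MatchEvidence(pattern_id=pid, start=s, end=e, snippet=snippet))
    evidence.sort(key=lambda ev: (ev.start, ev.end, ev.pattern_id))
    return RobCall(
        doc_id=document.doc_id,
        item=compiled.item,
        call=bool(evidence),
        evidence=tuple(evidence),
    )


def classify_corpus(
    corpus: Corpus | Iterable[Document],
    pattern_sets: Mapping[str, PatternSet],
) -> list[RobCall]:
    """Classify every document for every item (3 calls per document).

    Deterministic: documents are processed in ``doc_id`` order and items in
    the fixed order randomization, blinding, samplesize.
    """
    missing = [item for item in ITEMS if item not in pattern_sets]
    if missing:
        raise ValueError(f"pattern sets missing item(s): {missing}")
    compiled = {item: pattern_sets[item].compiled() for item in ITEMS}
    documents = sorted(corpus, key=lambda d: d.doc_id)
    calls: list[RobCall] = []
    for doc in documents:
        for item in ITEMS:
            calls.append(detect(doc, compiled[item]))
    return calls
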