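"""Passage extraction: dictionary matching and context-window construction.

The matcher tags every dictionary term occurring at a word boundary in
the article text (case-insensitive; hyphens inside dictionary terms match
either a hyphen or a space in text, so "African-American" also matches
"African American"). Overlapping candidates are resolved longest-match
first, then leftmost, so "type 2 diabetes" wins over its substring
"diabetes".

Each tagged mention is wrapped into a :class:`Passage` with up to 10
context tokens on either side. For the stage/ethnicity task windows are
cut at sentence boundaries (``within_sentence``); for the phenotype task
they may cross sentences (``cross_sentence``).
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from typing import Literal

from .corpus import Article, TermDictionary

TOKEN_RE = re.compile(r"\w+", re.UNICODE)

WindowPolicy = Literal["cross_sentence", "within_sentence"]
Location = Literal["title", "abstract", "body"]

MAX_CONTEXT_TOKENS = 10


@dataclass(frozen=True)
class Mention:
    """A dictionary-matched entity occurrence in an article's text."""

    doc_id: str
    surface: str
    canonical: str
    char_span: tuple[int, int]  # 0-based half-open into the document text
    location: Location
    section_title: str
    sentence_index: int

    def __post_init__(self) -> None:
        start, end = self.char_span
        if end <= start:
            raise ValueError(f"empty char span {self.char_span}")


@dataclass(frozen=True)
class Passage:
    """A mention plus its (<=10-token) left/right context windows.

    ``rel_doc_pos``/``rel_sec_pos`` are the mention's normalised character
    offsets from the start of the document / its enclosing region, and
    ``entity_doc_count`` the number of mentions of the same canonical
    entity in the article — position and frequency signals consumed by
    the feature schemas.
    """

    mention: Mention
    left_context: tuple[str, ...]
    right_context: tuple[str, ...]
    window_policy: WindowPolicy
    rel_doc_pos: float = 0.0
    rel_sec_pos: float = 0.0
    entity_doc_count: int = 1

    def __post_init__(self) -> None:
        if len(self.left_context) > MAX_CONTEXT_TOKENS:
            raise ValueError("left context exceeds 10 tokens")
        if len(self.right_context) > MAX_CONTEXT_TOKENS:
            raise ValueError("right context exceeds 10 tokens")

    @property
    def doc_id(self) -> str:
        return self.mention.doc_id

    @property
    def canonical(self) -> str:
        return self.mention.canonical

    def context_tokens(self) -> tuple[str, ...]:
        return self.left_context + self.right_context


# ---------------------------------------------------------------------------
# Document text layout
# ---------------------------------------------------------------------------

_SENT_BOUNDARY = re.compile(r"[.!?]+[\"')\]]*\s+(?=[A-Z0-9(\"'])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence spans: break after [.!?] followed by a capital/digit."""
    if not text:
        return []
    spans = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        spans.append((start, m.end()))
        start = m.end()
    spans.append((start, len(text)))
    # trim trailing whitespace from each span
    return [(s, s + len(text[s:e].rstrip())) for s, e in spans
            if len(text[s:e].rstrip()) > 0]


@dataclass
class DocumentText:
    """Concatenated article text with region and sentence annotations.

    Regions are laid out in order: title, abstract, then for each section
    its title and paragraphs, separated by single newlines. Char spans of
    mentions index into :attr:`text`.
    """

    text: str
    # (start, end, location, section_title) per region
    regions: list[tuple[int, int, Location, str]]
    sentences: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_article(cls, article: Article) -> "DocumentText":
        parts: list[str] = []
        regions: list[tuple[int, int, Location, str]] = []
        pos = 0

        def add(chunk: str, location: Location, section_title: str) -> None:
            nonlocal pos
            if not chunk:
                return
            if parts:
                parts.append("\n")
                pos += 1
            parts.append(chunk)
            regions.append((pos, pos + len(chunk), location, section_title))
            pos += len(chunk)

        add(article.title, "title", "")
        add(article.abstract, "abstract", "")
        for sec_title, paragraphs in article.sections:
            add(sec_title, "body", sec_title)
            for p in paragraphs:
                add(p, "body", sec_title)
        text = "".join(parts)
        doc = cls(text=text, regions=regions)
        for start, end, _, _ in regions:
            for s, e in split_sentences(text[start:end]):
                doc.sentences.append((start + s, start + e))
        return doc

    def _region_at(self, pos: int) -> tuple[int, int, Location, str]:
        for region in self.regions:
            if region[0] <= pos < region[1]:
                return region
        return (0, max(len(self.text), 1), "body", "")

    def location_at(self, pos: int) -> Location:
        return self._region_at(pos)[2]

    def section_title_at(self, pos: int) -> str:
        return self._region_at(pos)[3]

    def sentence_index_at(self, pos: int) -> int:
        starts = [s for s, _ in self.sentences]
        i = bisect.bisect_right(starts, pos) - 1
        return max(i, 0)

    def sentence_span_at(self, pos: int) -> tuple[int, int]:
        if not self.sentences:
            return (0, len(self.text))
        return self.sentences[self.sentence_index_at(pos)]


# ---------------------------------------------------------------------------
# Dictionary matching
# ---------------------------------------------------------------------------

def _term_pattern(term: str) -> re.Pattern:
    # hyphen <-> space equivalence inside multi-part terms
    parts = re.split(r"[\s\-]+", term.strip())
    body = r"[\s\-]+".join(re.escape(p) for p in parts if p)
    return re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE)


def match_mentions(article: Article, dictionary: TermDictionary) -> list[Mention]:
    """Tag all dictionary terms in the article text.

    Candidates from all terms are pooled and resolved longest-match-first,
    then leftmost; accepted matches never overlap. Returns mentions in
    document order.
    """
    doc = DocumentText.from_article(article)
    candidates: list[tuple[int, int, str]] = []  # (start, end, canonical)
    for term, canonical in dictionary.entries.items():
        for m in _term_pattern(term).finditer(doc.text):
            candidates.append((m.start(), m.end(), canonical))
    # longest first, then leftmost; deterministic final tie-break on canonical
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    taken: list[tuple[int, int]] = []
    accepted: list[tuple[int, int, str]] = []
    for start, end, canonical in candidates:
        if any(s < end and start < e for s, e in taken):
            continue
        taken.append((start, end))
        accepted.append((start, end, canonical))
    accepted.sort()
    mentions = []
    for start, end, canonical in accepted:
        mentions.append(Mention(
            doc_id=article.doc_id,
            surface=doc.text[start:end],
            canonical=canonical,
            char_span=(start, end),
            location=doc.location_at(start),
            section_title=doc.section_title_at(start),
            sentence_index=doc.sentence_index_at(start),
        ))
    return mentions


# ---------------------------------------------------------------------------
# Passage windows
# ---------------------------------------------------------------------------

def extract_passages(
    mentions: list[Mention],
    article: Article,
    policy: WindowPolicy = "cross_sentence",
) -> list[Passage]:
    """Build context windows of up to 10 tokens per side for each mention."""
    doc = DocumentText.from_article(article)
    tokens = [(m.group(), m.start(), m.end()) for m in TOKEN_RE.finditer(doc.text)]
    counts: dict[str, int] = {}
    for m in mentions:
        counts[m.canonical] = counts.get(m.canonical, 0) + 1

    passages = []
    doc_len = max(len(doc.text), 1)
    for mention in mentions:
        start, end = mention.char_span
        lo, hi = 0, doc_len
        if policy == "within_sentence":
            lo, hi = doc.sentence_span_at(start)
        left = [t for t, ts, te in tokens if te <= start and ts >= lo]
        right = [t for t, ts, te in tokens if ts >= end and te <= hi]
        region = doc._region_at(start)
        region_len = max(region[1] - region[0], 1)
        passages.append(Passage(
            mention=mention,
            left_context=tuple(left[-MAX_CONTEXT_TOKENS:]),
            right_context=tuple(right[:MAX_CONTEXT_TOKENS]),
            window_policy=policy,
            rel_doc_pos=min(start / doc_len, 1.0),
            rel_sec_pos=min((start - region[0]) / region_len, 1.0),
            entity_doc_count=counts[mention.canonical],
        ))
    return passages


def tokenize(text: str) -> list[str]:
    """Unicode word tokens (used by rule classifiers and feature schemas)."""
    return TOKEN_RE.findall(text)


__all__ = [
    "Mention", "Passage", "DocumentText", "match_mentions",
    "extract_passages", "split_sentences", "tokenize",
]
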