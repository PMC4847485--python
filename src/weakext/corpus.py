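"""Domain types and file I/O for articles, curated records, dictionaries, lexicons.

Articles come either in a minimal structured-XML dialect::

    <article>
      <article-title>...</article-title>
      <abstract><p>...</p></abstract>
      <sec><title>...</title><p>...</p>...</sec>
      ...
    </article>

or as plain text (empty title/abstract, one untitled section). Curated
records are tab-separated tables keyed by document ID, mirroring how
curated databases such as the GWAS Catalog publish their spreadsheets:
one row per curated fact, several rows per document.

All readers accept gzip-compressed files (by ``.gz`` suffix) and apply a
light typographic normalisation (curly quotes/dashes to ASCII, runs of
whitespace collapsed) so that curated tables and article text can be
compared on equal footing.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from lxml import etree

from .errors import DictionaryConflictError, ParseError, SchemaError

logger = logging.getLogger(__name__)

Stage = Literal["initial", "replication"]
STAGES: tuple[Stage, Stage] = ("initial", "replication")

_TYPOGRAPHY = str.maketrans({
    "‘": "'", "’": "'", "“": '"', "”": '"',
    "–": "-", "—": "-", "−": "-", " ": " ",
})

_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Collapse whitespace runs and map curly quotes/dashes to ASCII."""
    return _WS_RE.sub(" ", text.translate(_TYPOGRAPHY)).strip()


def fold(text: str) -> str:
    """Normalisation used for matching keys: casefold + typography + whitespace."""
    return normalize_text(text).casefold()


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Article:
    """A research article reduced to title, abstract and titled sections."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    sections: list[tuple[str, list[str]]] = field(default_factory=list)
    source_format: Literal["structured_xml", "plain_text"] = "structured_xml"

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("Article.doc_id must be non-empty")


@dataclass
class CuratedRecord:
    """Curated database fields for one document.

    For the phenotype task the record carries the curator-chosen
    disease/trait terms; for the stage/ethnicity task it carries the set
    of ``(stage, ethnicity)`` tuples. Original casing is retained for
    display; matching is done through :func:`fold`.
    """

    doc_id: str
    task: Literal["phenotype", "stage_ethnicity"]
    phenotype_terms: list[str] = field(default_factory=list)
    tuples: frozenset[tuple[Stage, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.task == "phenotype" and not self.phenotype_terms:
            raise ValueError(f"record {self.doc_id}: no phenotype terms")
        if self.task == "stage_ethnicity" and not self.tuples:
            raise ValueError(f"record {self.doc_id}: no stage/ethnicity tuples")
        for stage, _ in self.tuples:
            if stage not in STAGES:
                raise ValueError(f"record {self.doc_id}: invalid stage {stage!r}")

    @property
    def ethnicities(self) -> frozenset[str]:
        return frozenset(eth for _, eth in self.tuples)

    def ethnicities_for(self, stage: Stage) -> frozenset[str]:
        return frozenset(eth for s, eth in self.tuples if s == stage)


@dataclass
class TermDictionary:
    """Many-to-one mapping from case-folded surface terms to canonical entities."""

    entries: dict[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"dictionary {self.name!r} is empty")
        for term in self.entries:
            if not term:
                raise ValueError(f"dictionary {self.name!r} contains an empty term")

    def lookup(self, surface: str) -> str | None:
        return self.entries.get(fold(surface))

    @property
    def canonicals(self) -> frozenset[str]:
        return frozenset(self.entries.values())

    def surfaces_of(self, canonical: str) -> list[str]:
        return sorted(t for t, c in self.entries.items() if c == canonical)


@dataclass
class RuleLexicon:
    """A flat set of case-folded cue terms used by a rule classifier."""

    terms: frozenset[str]
    purpose: Literal["sample_description", "initial_cue", "replication_cue"]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"lexicon for {self.purpose!r} is empty")


# ---------------------------------------------------------------------------
# Article I/O
# ---------------------------------------------------------------------------

def read_article(
    path: str | Path,
    format: Literal["structured_xml", "plain_text"] = "structured_xml",
    doc_id: str | None = None,
) -> Article:
    """Read an article file in the minimal XML dialect or as plain text.

    ``doc_id`` defaults to the file stem (without ``.gz``/format suffixes).
    """
    path = Path(path)
    if doc_id is None:
        doc_id = path.name
        for suffix in (".gz", ".xml", ".txt"):
            if doc_id.endswith(suffix):
                doc_id = doc_id[: -len(suffix)]
    with _open_text(path) as fh:
        raw = fh.read()
    if not raw.strip():
        raise ParseError(f"{path}: empty input")

    if format == "plain_text":
        paragraphs = [normalize_text(p) for p in raw.split("\n\n")]
        paragraphs = [p for p in paragraphs if p]
        return Article(doc_id=doc_id, title="", abstract="",
                       sections=[("", paragraphs)], source_format="plain_text")

    try:
        root = etree.fromstring(raw.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: malformed XML at line {exc.lineno}: {exc.msg}") from exc
    if root.tag != "article":
        raise ParseError(f"{path}: root element is <{root.tag}>, expected <article>")

    def text_of(el) -> str:
        return normalize_text("".join(el.itertext())) if el is not None else ""

    title = text_of(root.find("article-title"))
    abstract_el = root.find("abstract")
    if abstract_el is not None:
        parts = [normalize_text(p.text or "") for p in abstract_el.findall("p")]
        abstract = " ".join(x for x in parts if x) or text_of(abstract_el)
    else:
        abstract = ""
    sections: list[tuple[str, list[str]]] = []
    for sec in root.findall("sec"):
        sec_title = text_of(sec.find("title"))
        paragraphs = [normalize_text("".join(p.itertext())) for p in sec.findall("p")]
        sections.append((sec_title, [p for p in paragraphs if p]))
    return Article(doc_id=doc_id, title=title, abstract=abstract,
                   sections=sections, source_format="structured_xml")


def write_article(article: Article, path: str | Path) -> None:
    """Serialise an article to the minimal XML dialect (round-trips with read)."""
    root = etree.Element("article")
    etree.SubElement(root, "article-title").text = article.title
    abstract = etree.SubElement(root, "abstract")
    if article.abstract:
        etree.SubElement(abstract, "p").text = article.abstract
    for sec_title, paragraphs in article.sections:
        sec = etree.SubElement(root, "sec")
        etree.SubElement(sec, "title").text = sec_title
        for p in paragraphs:
            etree.SubElement(sec, "p").text = p
    data = etree.tostring(root, pretty_print=True, encoding="unicode")
    with _open_text(path, "wt") as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# Curated tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {
    "phenotype": ["DOC_ID", "DISEASETRAIT"],
    "stage_ethnicity": ["DOC_ID", "STAGE", "ETHNICITY"],
}


def read_curated_table(
    path: str | Path,
    task: Literal["phenotype", "stage_ethnicity"],
    ethnicity_aliases: dict[str, str] | None = None,
) -> list[CuratedRecord]:
    """Read a curated TSV table into one merged record per document.

    Rows sharing a ``DOC_ID`` are merged (multiple phenotype terms /
    multiple tuples per document). Rows with blank required cells are
    skipped with a warning. ``ethnicity_aliases`` is an optional
    case-folded alias table applied to ethnicity values, for spreadsheets
    whose top-level names vary in word order (e.g. "North African/Middle
    East" vs "Middle East/North African").
    """
    required = _REQUIRED_COLUMNS[task]
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    aliases = {fold(k): v for k, v in (ethnicity_aliases or {}).items()}
    by_doc: dict[str, dict] = {}
    for idx, row in df.iterrows():
        values = {c: normalize_text(str(row[c])) for c in required}
        if any(not v for v in values.values()):
            logger.warning("%s: row %d skipped (blank required cell)", path, idx + 2)
            continue
        doc_id = values["DOC_ID"]
        slot = by_doc.setdefault(doc_id, {"terms": [], "keys": set(), "tuples": set()})
        if task == "phenotype":
            term = values["DISEASETRAIT"]
            if fold(term) not in slot["keys"]:
                slot["keys"].add(fold(term))
                slot["terms"].append(term)
        else:
            stage = fold(values["STAGE"])
            if stage not in STAGES:
                raise SchemaError(
                    f"{path}: row {idx + 2}: invalid STAGE value {values['STAGE']!r}")
            eth = values["ETHNICITY"]
            eth = aliases.get(fold(eth), eth)
            slot["tuples"].add((stage, eth))

    records = []
    for doc_id in sorted(by_doc):
        slot = by_doc[doc_id]
        if task == "phenotype":
            records.append(CuratedRecord(doc_id, "phenotype",
                                         phenotype_terms=slot["terms"]))
        else:
            records.append(CuratedRecord(doc_id, "stage_ethnicity",
                                         tuples=frozenset(slot["tuples"])))
    return records


def write_curated_table(records: Iterable[CuratedRecord], path: str | Path) -> None:
    """Write curated records back to the TSV formats accepted by the reader."""
    records = list(records)
    rows: list[dict] = []
    if records and records[0].task == "phenotype":
        for rec in records:
            for term in rec.phenotype_terms:
                rows.append({"DOC_ID": rec.doc_id, "DISEASETRAIT": term})
        columns = _REQUIRED_COLUMNS["phenotype"]
    else:
        for rec in records:
            for stage, eth in sorted(rec.tuples):
                rows.append({"DOC_ID": rec.doc_id, "STAGE": stage, "ETHNICITY": eth})
        columns = _REQUIRED_COLUMNS["stage_ethnicity"]
    df = pd.DataFrame(rows, columns=columns)
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dictionaries and lexicons
# ---------------------------------------------------------------------------

def load_dictionary(path: str | Path, name: str | None = None) -> TermDictionary:
    """Load a two-column TSV term dictionary (surface term -> canonical entity).

    Terms are case-folded; duplicate identical rows collapse silently; a
    term mapped to two different entities is a hard error (silent
    conflicts would corrupt weak labels downstream).
    """
    path = Path(path)
    entries: dict[str, str] = {}
    conflicts: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(f"{path}:{lineno}: expected 2 tab-separated columns")
            term, entity = fold(parts[0]), normalize_text(parts[1])
            if not term or not entity:
                raise SchemaError(f"{path}:{lineno}: empty term or entity")
            if term in entries and entries[term] != entity:
                conflicts.append(term)
            entries[term] = entity
    if conflicts:
        raise DictionaryConflictError(
            f"{path}: conflicting entries for term(s): {sorted(set(conflicts))}")
    if not entries:
        raise ParseError(f"{path}: empty dictionary")
    return TermDictionary(entries=entries, name=name or path.stem)


def dump_dictionary(dictionary: TermDictionary, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for term in sorted(dictionary.entries):
            fh.write(f"{term}\t{dictionary.entries[term]}\n")


def load_lexicon(
    path: str | Path,
    purpose: Literal["sample_description", "initial_cue", "replication_cue"],
) -> RuleLexicon:
    """Load a one-term-per-line lexicon; blank lines and ``#`` comments ignored."""
    terms = set()
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                terms.add(fold(line))
    return RuleLexicon(terms=frozenset(terms), purpose=purpose)


def dump_lexicon(lexicon: RuleLexicon, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for term in sorted(lexicon.terms):
            fh.write(term + "\n")
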