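"""Literature-record ingestion, sentence splitting, and entity assignment.

Records come either from MEDLINE/PubMed XML or a JSONL fallback (one object
per line: ``id``, ``title``, ``abstract``, ``mesh``). Abstracts are split into
sentences by a deterministic rule-based splitter, dictionary keywords and
entity surface names are matched with the same token-boundary longest-match
rule, and documents mentioning no gene and no disease are dropped.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple, Optional, Union

from lxml import etree

from ._matching import PhraseMatcher, normalize_term
from .mesh import Dictionary

logger = logging.getLogger(__name__)

#: A mention site: ("title", None), ("mesh", None) or ("sentence", i).
Mention = tuple[str, Optional[int]]


class RawRecord(NamedTuple):
    doc_id: str
    title: str
    abstract: str
    mesh_terms: tuple[str, ...]


@dataclass
class Document:
    """One literature record with its entity mention sites resolved."""

    doc_id: str
    title: str
    sentences: list[str]
    mesh_terms: list[str]
    gene_mentions: dict[str, set[Mention]] = field(default_factory=dict)
    disease_mentions: dict[str, set[Mention]] = field(default_factory=dict)

    def mentions_of(self, entity_id: str) -> set[Mention]:
        return self.gene_mentions.get(entity_id) or self.disease_mentions.get(entity_id, set())


@dataclass
class EntityLexicon:
    """entity_id -> set of case-normalized surface names."""

    names: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        cleaned = {}
        for entity_id, surface in self.names.items():
            forms = frozenset(normalize_term(s) for s in surface if normalize_term(s))
            if not forms:
                raise ValueError(f"entity {entity_id!r} has no non-empty surface name")
            cleaned[entity_id] = forms
        self.names = cleaned

    def __len__(self) -> int:
        return len(self.names)

    @property
    def entity_ids(self) -> list[str]:
        return sorted(self.names)

    @classmethod
    def from_tsv(cls, path: Union[str, Path, IO[str]]) -> "EntityLexicon":
        """Read ``entity_id<TAB>name[|name...]`` lines; ``#`` comments."""
        handle = open(path, encoding="utf-8") if not hasattr(path, "read") else path
        names: dict[str, set[str]] = {}
        try:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"malformed lexicon record at line {lineno}: {line!r}")
                entity_id, surface = parts
                if entity_id in names:
                    raise ValueError(f"duplicate entity id {entity_id!r} at line {lineno}")
                names[entity_id] = set(surface.split("|"))
        finally:
            if handle is not path:
                handle.close()
        return cls({k: frozenset(v) for k, v in names.items()})

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = [f"{eid}\t{'|'.join(sorted(self.names[eid]))}\n" for eid in sorted(self.names)]
        Path(path).write_text("".join(lines), encoding="utf-8")


def _matcher(obj, phrases: Iterable[str]) -> PhraseMatcher:
    cached = getattr(obj, "_phrase_matcher", None)
    if cached is None:
        cached = PhraseMatcher(phrases)
        obj._phrase_matcher = cached
    return cached


# --- sentence splitting -----------------------------------------------------

# tokens before a period that do not end a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "vs", "cf", "et", "al", "fig", "figs", "eq", "eqs", "ref",
    "refs", "dr", "mr", "mrs", "ms", "prof", "st", "no", "ca", "approx",
    "sp", "spp", "subsp", "var",
}
_BOUNDARY_RE = re.compile(r"([.?!]+)\s+(?=[A-Z0-9])")
_LAST_WORD_RE = re.compile(r"(\S+)$")


def split_sentences(text: str) -> list[str]:
    """Deterministic rule-based sentence splitting.

    Splits at terminal ``.?!`` followed by whitespace and an uppercase letter
    or digit, unless the preceding token is a known abbreviation or a single
    initial (guards "E. coli", "et al.", "i.e." and the like).
    """
    text = text.strip()
    if not text:
        return []
    sentences = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        if "." in m.group(1):
            before = _LAST_WORD_RE.search(text[: m.start() + len(m.group(1)) - 1])
            word = before.group(1).rstrip(".").lower() if before else ""
            word = word.lstrip("([\"'")
            if word in _ABBREVIATIONS or (len(word) == 1 and word.isalpha()):
                continue
        chunk = text[start : m.start() + len(m.group(1))].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# --- record readers ---------------------------------------------------------

def _iter_medline_xml(source) -> Iterator[tuple[int, str, str, str, tuple[str, ...]]]:
    tree = etree.parse(source)
    articles = tree.iter("PubmedArticle")
    for pos, art in enumerate(articles):
        cit = art.find("MedlineCitation")
        if cit is None:
            raise ValueError(f"malformed record at position {pos}: missing MedlineCitation")
        pmid = cit.findtext("PMID")
        if pmid is None:
            raise ValueError(f"malformed record at position {pos}: missing PMID")
        title = cit.findtext("Article/ArticleTitle") or ""
        abstract = " ".join(
            t.strip() for t in
            (el.text or "" for el in cit.findall("Article/Abstract/AbstractText"))
            if t.strip()
        )
        mesh = tuple(
            el.text.strip() for el in cit.findall("MeshHeadingList/MeshHeading/DescriptorName")
            if el.text and el.text.strip()
        )
        yield pos, pmid.strip(), title.strip(), abstract, mesh


def _iter_jsonl(handle: IO[str]) -> Iterator[tuple[int, str, str, str, tuple[str, ...]]]:
    for pos, line in enumerate(handle):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed record at position {pos}: {exc}") from exc
        if "id" not in obj or "title" not in obj:
            raise ValueError(f"malformed record at position {pos}: missing 'id' or 'title'")
        yield pos, str(obj["id"]), obj["title"], obj.get("abstract") or "", tuple(obj.get("mesh") or ())


def read_corpus(source: Union[str, Path, IO], format: str = "jsonl") -> Iterator[RawRecord]:
    """Yield records as (doc_id, title, abstract, mesh_terms) tuples.

    Records missing an abstract yield an empty abstract (logged); a duplicate
    doc_id is skipped with a warning.
    """
    if format == "medline_xml":
        raw = _iter_medline_xml(str(source) if isinstance(source, Path) else source)
    elif format == "jsonl":
        if hasattr(source, "read"):
            raw = _iter_jsonl(source)
        else:
            raw = _iter_jsonl(open(source, encoding="utf-8"))
    else:
        raise ValueError(f"unknown corpus format {format!r}; expected 'medline_xml' or 'jsonl'")

    seen: set[str] = set()
    for pos, doc_id, title, abstract, mesh in raw:
        if doc_id in seen:
            logger.warning("duplicate doc_id %r at position %d; skipped", doc_id, pos)
            continue
        seen.add(doc_id)
        if not abstract:
            logger.info("record %r has no abstract", doc_id)
        yield RawRecord(doc_id, title, abstract, mesh)


# --- matching ---------------------------------------------------------------

def match_keywords(text: str, dictionary: Dictionary) -> Counter[str]:
    """Count dictionary keyword occurrences in text.

    Case-insensitive, on token boundaries, longest match first and
    non-overlapping; multi-word keywords must be contiguous token runs.
    """
    return _matcher(dictionary, dictionary.entries).count(text)


def match_entities(
    title: str,
    sentences: list[str],
    mesh_terms: list[str],
    lexicon: EntityLexicon,
) -> dict[str, set[Mention]]:
    """Per entity, every field (title / mesh / sentence i) naming it."""
    if not len(lexicon):
        return {}
    name_to_ids: dict[str, set[str]] = {}
    for eid, forms in lexicon.names.items():
        for form in forms:
            name_to_ids.setdefault(form, set()).add(eid)
    matcher = _matcher(lexicon, name_to_ids)
    mentions: dict[str, set[Mention]] = {}

    def record(text: str, site: Mention) -> None:
        for name in matcher.count(text):
            for eid in name_to_ids[name]:
                mentions.setdefault(eid, set()).add(site)

    record(title, ("title", None))
    for term in mesh_terms:
        record(term, ("mesh", None))
    for i, sentence in enumerate(sentences):
        record(sentence, ("sentence", i))
    return mentions


# --- corpus assembly --------------------------------------------------------

@dataclass
class Corpus:
    """Documents retained after entity filtering plus the entity->doc index."""

    documents: dict[str, Document]
    gene_index: dict[str, list[str]]
    disease_index: dict[str, list[str]]

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        # allows tuple-style unpacking: documents, index
        yield self.documents
        yield {**self.gene_index, **self.disease_index}


def build_corpus(
    records: Iterable[RawRecord],
    gene_lexicon: EntityLexicon,
    disease_lexicon: EntityLexicon,
) -> Corpus:
    """Split, match and filter: keep only records mentioning some entity.

    The index maps every lexicon entity (mentioned or not) to the sorted
    doc_ids mentioning it; one document may serve several entities.
    """
    overlap = set(gene_lexicon.names) & set(disease_lexicon.names)
    if overlap:
        raise ValueError(f"gene and disease lexicons share ids: {sorted(overlap)[:5]}")
    documents: dict[str, Document] = {}
    gene_index: dict[str, list[str]] = {eid: [] for eid in gene_lexicon.names}
    disease_index: dict[str, list[str]] = {eid: [] for eid in disease_lexicon.names}
    for rec in records:
        sentences = split_sentences(rec.abstract)
        gm = match_entities(rec.title, sentences, list(rec.mesh_terms), gene_lexicon)
        dm = match_entities(rec.title, sentences, list(rec.mesh_terms), disease_lexicon)
        if not gm and not dm:
            continue
        documents[rec.doc_id] = Document(
            doc_id=rec.doc_id,
            title=rec.title,
            sentences=sentences,
            mesh_terms=list(rec.mesh_terms),
            gene_mentions=gm,
            disease_mentions=dm,
        )
        for eid in gm:
            gene_index[eid].append(rec.doc_id)
        for eid in dm:
            disease_index[eid].append(rec.doc_id)
    for index in (gene_index, disease_index):
        for eid in index:
            index[eid].sort()
    return Corpus(documents, gene_index, disease_index)
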