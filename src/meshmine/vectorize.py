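"""Per-document location vectors and their weighted combination.

A document contributes three kinds of keyword vectors: title counts, one
count vector per abstract sentence, and a binary vector over its indexed
MeSH terms. They are combined into one representative vector per
(document, target entity) pair with location weights -- MeSH terms weigh most
(they are curated annotations), titles next, and abstract sentences weigh
more when the target entity is co-mentioned in the same sentence:

    raw[k] = w_title * title[k]
           + sum_i (w_abs_with if entity in sentence i else w_abs_without) * sent_i[k]
           + w_mesh * mesh[k]

The combined vector is normalized to unit sum, optionally after a log(1+v)
transform that damps article-length effects.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .corpus import Document, Mention, match_keywords
from .mesh import Dictionary


@dataclass
class WeightConfig:
    """Location weights for vector combination (defaults per the method)."""

    w_mesh: float = 3.0
    w_title: float = 2.0
    w_abs_with: float = 2.0
    w_abs_without: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.w_mesh, self.w_title, self.w_abs_with, self.w_abs_without)
        if any(v < 0 for v in vals):
            raise ValueError("location weights must be non-negative")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one location weight must be positive")

    @classmethod
    def uniform(cls) -> "WeightConfig":
        """All locations weigh 1: the 'no weight matrix' ablation."""
        return cls(1.0, 1.0, 1.0, 1.0)

    def scaled(self, c: float) -> "WeightConfig":
        return WeightConfig(c * self.w_mesh, c * self.w_title, c * self.w_abs_with, c * self.w_abs_without)


@dataclass
class LocationVectors:
    title_vec: Counter
    sentence_vecs: list[Counter]
    mesh_vec: dict[str, int]


@dataclass
class DocVector:
    """Sparse normalized keyword->weight map for one (document, entity)."""

    entries: dict[str, float]
    norm_method: str = "sum1"

    def __len__(self) -> int:
        return len(self.entries)

    def total(self) -> float:
        return sum(self.entries.values())


def build_location_vectors(doc: Document, dictionary: Dictionary) -> LocationVectors:
    """Match dictionary keywords in each field of the document.

    The MeSH-term vector is binary: 1 if the keyword occurs among the
    document's indexed terms (however many times), else absent.
    """
    title_vec = match_keywords(doc.title, dictionary)
    sentence_vecs = [match_keywords(s, dictionary) for s in doc.sentences]
    mesh_vec: dict[str, int] = {}
    for term in doc.mesh_terms:
        for kw in match_keywords(term, dictionary):
            mesh_vec[kw] = 1
    return LocationVectors(title_vec, sentence_vecs, mesh_vec)


def combine(
    locvecs: LocationVectors,
    weights: WeightConfig,
    entity_mentions: Iterable[Mention] = (),
) -> dict[str, float]:
    """Weighted sum of the location vectors for one target entity.

    ``entity_mentions`` are this document's mention sites of the single
    target entity; a ("sentence", i) site switches sentence i to the
    co-mention weight.
    """
    mention_sentences = {i for field_, i in entity_mentions if field_ == "sentence"}
    raw: dict[str, float] = {}
    for kw, n in locvecs.title_vec.items():
        raw[kw] = raw.get(kw, 0.0) + weights.w_title * n
    for i, svec in enumerate(locvecs.sentence_vecs):
        w = weights.w_abs_with if i in mention_sentences else weights.w_abs_without
        for kw, n in svec.items():
            raw[kw] = raw.get(kw, 0.0) + w * n
    for kw, b in locvecs.mesh_vec.items():
        raw[kw] = raw.get(kw, 0.0) + weights.w_mesh * b
    return {kw: v for kw, v in raw.items() if v > 0}


def normalize(raw: dict[str, float], method: str = "log") -> DocVector:
    """Scale to unit sum, either directly (sum1) or after log(1+v) (log)."""
    if any(v < 0 for v in raw.values()):
        raise ValueError("raw vector entries must be non-negative")
    if method == "sum1":
        transformed = {k: v for k, v in raw.items() if v > 0}
    elif method == "log":
        transformed = {k: math.log1p(v) for k, v in raw.items() if v > 0}
    else:
        raise ValueError(f"unknown normalization method {method!r}; expected 'sum1' or 'log'")
    total = sum(transformed.values())
    if total == 0:
        return DocVector({}, norm_method=method)
    return DocVector({k: v / total for k, v in transformed.items()}, norm_method=method)


def vectorize_for_entity(
    doc: Document,
    dictionary: Dictionary,
    entity_id: str,
    weights: Optional[WeightConfig] = None,
    norm_method: str = "log",
    locvecs: Optional[LocationVectors] = None,
) -> DocVector:
    """Full per-(document, entity) vectorization; locvecs may be precomputed."""
    if weights is None:
        weights = WeightConfig()
    if locvecs is None:
        locvecs = build_location_vectors(doc, dictionary)
    raw = combine(locvecs, weights, doc.mentions_of(entity_id))
    return normalize(raw, norm_method)
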