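"""Entity profiles: TW-scaled aggregates of an entity's document vectors.

A gene's (or disease's) profile sums keyword weights over all document
vectors built for that entity and multiplies each keyword's total by its term
weight TW. Entities with no documents keep an empty profile so the
association table stays complete over the lexicons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

from .corpus import Corpus
from .vectorize import DocVector
from .weighting import TermWeights


@dataclass
class EntityProfile:
    entity_id: str
    kind: str  # {gene, disease}
    vec: dict[str, float]
    n_docs: int = 0

    def __len__(self) -> int:
        return len(self.vec)


def build_profile(
    entity_id: str,
    kind: str,
    doc_vectors: Iterable[DocVector],
    tw: TermWeights,
) -> EntityProfile:
    """vec[k] = (sum over this entity's doc vectors of entry k) * tw[k].

    Keywords without a TW in this scope were never observed here and are
    dropped (they would contribute zero weight).
    """
    sums: dict[str, float] = {}
    n_docs = 0
    for dv in doc_vectors:
        n_docs += 1
        for kw, v in dv.entries.items():
            sums[kw] = sums.get(kw, 0.0) + v
    vec = {}
    for kw, s in sums.items():
        w = tw.get(kw)
        if w > 0 and s > 0:
            vec[kw] = s * w
    return EntityProfile(entity_id, kind, vec, n_docs)


def build_all_profiles(
    corpus: Corpus,
    doc_vectors: Mapping[tuple[str, str], DocVector],
    gene_tw: TermWeights,
    disease_tw: TermWeights,
) -> tuple[dict[str, EntityProfile], dict[str, EntityProfile]]:
    """One profile per lexicon entity (empty for unmentioned ones).

    ``doc_vectors`` maps (doc_id, entity_id) to the entity-specific vector of
    that document. Profiles are returned in sorted entity_id order.
    """
    gene_profiles: dict[str, EntityProfile] = {}
    for eid in sorted(corpus.gene_index):
        vecs = [doc_vectors[(doc_id, eid)] for doc_id in corpus.gene_index[eid]]
        gene_profiles[eid] = build_profile(eid, "gene", vecs, gene_tw)
    disease_profiles: dict[str, EntityProfile] = {}
    for eid in sorted(corpus.disease_index):
        vecs = [doc_vectors[(doc_id, eid)] for doc_id in corpus.disease_index[eid]]
        disease_profiles[eid] = build_profile(eid, "disease", vecs, disease_tw)
    return gene_profiles, disease_profiles


def write_profiles(profiles: Mapping[str, EntityProfile], path: Union[str, Path]) -> None:
    """Sparse triplet TSV: ``entity_id<TAB>keyword<TAB>weight``."""
    lines = []
    for eid in sorted(profiles):
        prof = profiles[eid]
        for kw in sorted(prof.vec):
            lines.append(f"{eid}\t{kw}\t{prof.vec[kw]:.10g}\n")
    Path(path).write_text("".join(lines), encoding="utf-8")
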