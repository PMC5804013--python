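"""End-to-end wiring: corpus -> vectors -> TW -> profiles -> scores -> PR.

:func:`run_pipeline` executes the whole flow on in-memory inputs and returns
every intermediate product, so ablations (uniform location weights, PWK off,
sum1 vs log normalization, joint vs split IDF scope) are plain option
toggles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .association import DEFAULT_BIN_EDGES, bin_distribution, score_all
from .corpus import Corpus, EntityLexicon, RawRecord, build_corpus
from .evaluation import GoldStandard, pr_curve
from .mesh import Dictionary
from .profiles import EntityProfile, build_all_profiles
from .vectorize import WeightConfig, build_location_vectors, combine, normalize
from .weighting import CorpusStats, TermWeights, corpus_sums, term_weights


@dataclass
class PipelineOptions:
    """Tunable knobs of the scoring pipeline (defaults are the method's)."""

    weights: WeightConfig = field(default_factory=WeightConfig)
    norm_method: str = "log"  # {log, sum1}
    use_pwk: bool = True
    idf_scope: str = "split"  # {split, joint}
    thresholds: Optional[Sequence[float]] = None
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES

    def without_weight_matrix(self) -> "PipelineOptions":
        return replace(self, weights=WeightConfig.uniform())


@dataclass
class PipelineResult:
    corpus: Corpus
    gene_tw: TermWeights
    disease_tw: TermWeights
    gene_profiles: dict[str, EntityProfile]
    disease_profiles: dict[str, EntityProfile]
    table: pd.DataFrame
    curve: Optional[pd.DataFrame]
    bins: pd.DataFrame
    options: PipelineOptions


def build_doc_vectors(
    corpus: Corpus,
    dictionary: Dictionary,
    options: PipelineOptions,
) -> tuple[dict[tuple[str, str], object], dict[tuple[str, str], object]]:
    """Entity-specific document vectors for the gene and disease scopes.

    Location vectors are matched once per document; the combination step is
    entity-specific because sentence weights depend on co-mention of the
    target entity.
    """
    locvec_cache = {
        doc_id: build_location_vectors(doc, dictionary)
        for doc_id, doc in corpus.documents.items()
    }

    def vectors_for(index: dict[str, list[str]], mentions_attr: str):
        out = {}
        for eid, doc_ids in index.items():
            for doc_id in doc_ids:
                doc = corpus.documents[doc_id]
                mentions = getattr(doc, mentions_attr).get(eid, set())
                raw = combine(locvec_cache[doc_id], options.weights, mentions)
                out[(doc_id, eid)] = normalize(raw, options.norm_method)
        return out

    gene_vecs = vectors_for(corpus.gene_index, "gene_mentions")
    disease_vecs = vectors_for(corpus.disease_index, "disease_mentions")
    return gene_vecs, disease_vecs


def run_pipeline(
    records: Iterable[RawRecord],
    dictionary: Dictionary,
    gene_lexicon: EntityLexicon,
    disease_lexicon: EntityLexicon,
    gold: Optional[GoldStandard] = None,
    options: Optional[PipelineOptions] = None,
) -> PipelineResult:
    """Run the full scoring flow; evaluation only if a gold standard is given."""
    options = options or PipelineOptions()
    corpus = build_corpus(records, gene_lexicon, disease_lexicon)
    gene_vecs, disease_vecs = build_doc_vectors(corpus, dictionary, options)

    if options.idf_scope == "joint":
        pooled = corpus_sums(list(gene_vecs.values()) + list(disease_vecs.values()), scope="joint")
        gene_stats = disease_stats = pooled
    elif options.idf_scope == "split":
        gene_stats = corpus_sums(gene_vecs.values(), scope="genes")
        disease_stats = corpus_sums(disease_vecs.values(), scope="diseases")
    else:
        raise ValueError(f"unknown idf_scope {options.idf_scope!r}; expected 'split' or 'joint'")

    gene_tw = term_weights(gene_stats, dictionary, use_pwk=options.use_pwk)
    disease_tw = term_weights(disease_stats, dictionary, use_pwk=options.use_pwk)
    gene_profiles, disease_profiles = build_all_profiles(
        corpus, {**gene_vecs, **disease_vecs}, gene_tw, disease_tw
    )
    table = score_all(gene_profiles, disease_profiles, gold)
    curve = pr_curve(table, gold, options.thresholds) if gold and len(gold) else None
    bins = bin_distribution(table, options.bin_edges)
    return PipelineResult(
        corpus=corpus,
        gene_tw=gene_tw,
        disease_tw=disease_tw,
        gene_profiles=gene_profiles,
        disease_profiles=disease_profiles,
        table=table,
        curve=curve,
        bins=bins,
        options=options,
    )
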