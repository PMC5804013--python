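"""Synthetic study generator: toy MeSH tree, corpus with planted signal, gold set.

The generator emulates the statistical structure the method exploits: each
gene and each disease carries a keyword signature, and every known (gene,
disease) pair shares a fixed fraction theta of its signature. Signal shows up
where the method looks for it -- titles, abstract sentences (with per-sentence
entity co-mention) and the indexed MeSH-term list -- diluted by off-signature
noise keywords. Signatures are drawn from deep tree nodes (depth >= 5) by
default so the PWK penalty does not confound signal-recovery checks; shallow
generic confounder keywords can be planted explicitly to exercise the PWK
ablation.

Everything is driven by one seeded pseudorandom stream, so a config + seed
reproduces the study bit-identically, and emitted files use exactly the
formats the pipeline consumes (JSONL corpus, tabular dictionary, lexicon TSV,
gold TSV).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .corpus import EntityLexicon, RawRecord
from .evaluation import GoldStandard, precision_at_rank
from .mesh import Dictionary, TreePosition
from .pipeline import PipelineOptions, PipelineResult, run_pipeline


@dataclass
class SimConfig:
    """Study-generator parameters.

    theta is the fraction of a signature shared by a known pair; noise_rate
    the probability a sentence keyword slot is filled with a random
    off-signature keyword; co_mention_prob the chance a sentence also names
    the document's target entity.
    """

    n_genes: int = 50
    n_diseases: int = 20
    n_known_pairs: int = 30
    signature_size: int = 10
    theta: float = 0.8
    docs_per_entity: int = 5
    sentences_per_doc: int = 4
    keywords_per_sentence: int = 5
    noise_rate: float = 0.1
    co_mention_prob: float = 0.5
    tree_depth: int = 6
    tree_branching: int = 3
    categories: tuple[str, ...] = ("A", "B", "C", "D", "F")
    signature_min_depth: int = 5
    n_confounders: int = 0  # shallow generic keywords planted in every doc
    signal_in_sentences: bool = True  # False: sentences carry only noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_diseases", "n_known_pairs", "signature_size",
                     "docs_per_entity", "sentences_per_doc", "keywords_per_sentence"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_known_pairs > self.n_genes * self.n_diseases:
            raise ValueError("n_known_pairs exceeds the gene x disease cross-product")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0, 1)")
        if not 0.0 <= self.co_mention_prob <= 1.0:
            raise ValueError("co_mention_prob must lie in [0, 1]")
        if self.tree_depth < 2 or self.tree_branching < 2:
            raise ValueError("tree_depth and tree_branching must both be >= 2")


@dataclass
class Study:
    """In-memory synthetic study: everything the pipeline consumes."""

    dictionary: Dictionary
    records: list[RawRecord]
    gene_lexicon: EntityLexicon
    disease_lexicon: EntityLexicon
    gold: GoldStandard
    signatures: dict[str, tuple[str, ...]]
    config: SimConfig


def generate_tree(cfg: SimConfig) -> Dictionary:
    """Complete b-ary keyword tree under the configured categories.

    Keyword names encode their tree position (e.g. node A01.02 is keyword
    ``kwa0102``) for debuggability; given the same config the fixture is
    bit-identical.
    """
    entries: dict[str, frozenset[TreePosition]] = {}
    for cat in cfg.categories:
        # level 2 nodes have single-segment tree numbers like "A01"
        frontier = [f"{cat}{i + 1:02d}" for i in range(cfg.tree_branching)]
        for level in range(2, cfg.tree_depth + 1):
            for tree_number in frontier:
                name = "kw" + tree_number.replace(".", "").lower()
                entries[name] = frozenset({TreePosition(tree_number)})
            if level < cfg.tree_depth:
                frontier = [
                    f"{t}.{i + 1:02d}" for t in frontier for i in range(cfg.tree_branching)
                ]
    return Dictionary(entries, categories_kept=frozenset(cfg.categories))


def _sentence_text(tokens: Sequence[str]) -> str:
    text = " ".join(tokens)
    return text[:1].upper() + text[1:] + "."


def generate_study(cfg: SimConfig) -> Study:
    """Plant signatures, draw documents, and emit the matching gold standard."""
    rng = np.random.default_rng(cfg.seed)
    dictionary = generate_tree(cfg)

    depths = dictionary.keyword_depth
    max_depth = max(depths.values())
    min_sig_depth = min(cfg.signature_min_depth, max_depth)
    deep_vocab = sorted(kw for kw, d in depths.items() if d >= min_sig_depth)
    all_vocab = sorted(dictionary.entries)

    genes = [f"gene{i + 1:04d}" for i in range(cfg.n_genes)]
    diseases = [f"dis{i + 1:04d}" for i in range(cfg.n_diseases)]
    gene_lexicon = EntityLexicon({g: frozenset({g}) for g in genes})
    disease_lexicon = EntityLexicon({d: frozenset({d}) for d in diseases})

    pair_idx = rng.choice(cfg.n_genes * cfg.n_diseases, size=cfg.n_known_pairs, replace=False)
    known_pairs = sorted((genes[i // cfg.n_diseases], diseases[i % cfg.n_diseases]) for i in pair_idx)
    gold = GoldStandard.from_pairs(known_pairs)

    # sequential allocation from a shuffled deep-keyword pool keeps signatures
    # of unrelated entities disjoint by construction
    pool = list(rng.permutation(deep_vocab))
    n_shared = math.floor(cfg.theta * cfg.signature_size)

    def take(n: int) -> list[str]:
        if len(pool) < n:
            raise ValueError(
                "signature demand exceeds the deep-keyword vocabulary; "
                "increase tree_depth or tree_branching"
            )
        return [pool.pop() for _ in range(n)]

    signatures: dict[str, set[str]] = {e: set() for e in genes + diseases}
    for g, d in known_pairs:
        shared = take(n_shared)
        signatures[g].update(shared)
        signatures[d].update(shared)
    for entity in genes + diseases:
        deficit = cfg.signature_size - len(signatures[entity])
        if deficit > 0:
            signatures[entity].update(take(deficit))

    signature_union = set().union(*signatures.values()) if signatures else set()
    noise_vocab = sorted(set(all_vocab) - signature_union)
    if not noise_vocab:
        noise_vocab = all_vocab

    shallow = sorted(kw for kw, d in depths.items() if d <= 3 and kw not in signature_union)
    if cfg.n_confounders > len(shallow):
        raise ValueError("n_confounders exceeds the shallow off-signature vocabulary")
    confounders = list(rng.choice(shallow, size=cfg.n_confounders, replace=False)) if cfg.n_confounders else []

    records: list[RawRecord] = []
    counter = 0
    for entity in genes + diseases:
        sig = sorted(signatures[entity])
        for _ in range(cfg.docs_per_entity):
            counter += 1
            title_kws = list(rng.choice(sig, size=min(2, len(sig)), replace=False))
            title = _sentence_text([entity] + title_kws + confounders)
            sentences = []
            for _ in range(cfg.sentences_per_doc):
                tokens = []
                if rng.random() < cfg.co_mention_prob:
                    tokens.append(entity)
                for _ in range(cfg.keywords_per_sentence):
                    if not cfg.signal_in_sentences or rng.random() < cfg.noise_rate:
                        tokens.append(str(rng.choice(noise_vocab)))
                    else:
                        tokens.append(str(rng.choice(sig)))
                sentences.append(_sentence_text(tokens))
            mesh_terms = list(rng.choice(sig, size=min(3, len(sig)), replace=False)) + confounders
            records.append(
                RawRecord(
                    doc_id=f"doc{counter:06d}",
                    title=title,
                    abstract=" ".join(sentences),
                    mesh_terms=tuple(mesh_terms),
                )
            )

    return Study(
        dictionary=dictionary,
        records=records,
        gene_lexicon=gene_lexicon,
        disease_lexicon=disease_lexicon,
        gold=gold,
        signatures={e: tuple(sorted(s)) for e, s in signatures.items()},
        config=cfg,
    )


def write_study(study: Study, outdir: Union[str, Path]) -> Path:
    """Write corpus.jsonl, dict.tsv, genes.tsv, diseases.tsv, gold.tsv + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.dictionary.to_tabular(outdir / "dict.tsv")
    study.gene_lexicon.to_tsv(outdir / "genes.tsv")
    study.disease_lexicon.to_tsv(outdir / "diseases.tsv")
    study.gold.to_tsv(outdir / "gold.tsv")
    with open(outdir / "corpus.jsonl", "w", encoding="utf-8") as fh:
        for rec in study.records:
            fh.write(json.dumps({
                "id": rec.doc_id,
                "title": rec.title,
                "abstract": rec.abstract,
                "mesh": list(rec.mesh_terms),
            }, sort_keys=True) + "\n")
    manifest = {"config": asdict(study.config), "n_records": len(study.records)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return outdir


def summarize(result: PipelineResult, gold: GoldStandard) -> dict:
    """Headline numbers for one run: P/R at fixed thresholds, bins, top-|K|."""
    table = result.table
    summary: dict = {
        "n_pairs": int(len(table)),
        "n_known": len(gold),
        "top_k_precision": precision_at_rank(table, len(gold)) if len(gold) else math.nan,
        "bins": result.bins.to_dict("records"),
    }
    if result.curve is not None:
        for x in (0.1, 0.3, 0.5, 0.7, 0.9):
            row = result.curve[np.isclose(result.curve["threshold"], x)]
            if len(row):
                summary[f"precision_at_{x}"] = float(row["precision"].iloc[0])
                summary[f"recall_at_{x}"] = float(row["recall"].iloc[0])
    return summary


def run_end_to_end(
    cfg: SimConfig,
    options: Optional[PipelineOptions] = None,
    study: Optional[Study] = None,
) -> tuple[PipelineResult, dict]:
    """Generate (or reuse) a study, run the full pipeline, and summarize."""
    if study is None:
        study = generate_study(cfg)
    result = run_pipeline(
        study.records,
        study.dictionary,
        study.gene_lexicon,
        study.disease_lexicon,
        gold=study.gold,
        options=options,
    )
    return result, summarize(result, study.gold)
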