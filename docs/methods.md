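# Methods

## Model

`meshmine` treats gene–disease association as a vector-space retrieval
problem. The signal model is: documents about a gene and documents about a
disease that are biologically linked tend to use the same specific MeSH
vocabulary; documents about unrelated entities share mostly generic
vocabulary. The pipeline therefore (1) restricts attention to a controlled
dictionary, (2) represents each document as a location-weighted keyword
vector, (3) re-weights keywords by corpus rarity and tree specificity,
(4) aggregates per-entity profiles, and (5) ranks pairs by cosine similarity.

Assumptions worth stating explicitly:

- **Dictionary matching suffices.** Entities and keywords are found by
  case-insensitive, token-boundary, longest-match-first dictionary lookup.
  There is no named-entity disambiguation; a gene symbol that is also an
  English word will be over-matched. This mirrors the method's design and is
  adequate for corpora where entity names are distinctive.
- **Mention implies aboutness.** Every document mentioning an entity
  contributes to its profile with equal prior weight; relevance is modulated
  only through the location weights and normalization.
- **Cosine is the association measure.** Profiles are non-negative, so scores
  live in [0, 1] and Cauchy–Schwarz bounds them by 1. No significance is
  attached to an individual score; evaluation is rank-based against a gold
  standard.

## Pipeline stages and parameters

**Dictionary** (`mesh`). MeSH descriptors are read from the official XML or a
tabular dialect (`keyword<TAB>treenum[;treenum...]`). Depth counts the
category letter as level 1, so a tree number with *s* dot-separated segments
has depth *s* + 1; this makes the PWK threshold of 5 sit just below typical
specific disease terms while generic terms land at depths 2–4. A keyword with
several tree positions takes its **maximum** depth by default (most specific
placement; `depth_rule="min"` is available — MeSH polyhierarchy gives no
single canonical choice). The default category filter keeps {A, B, C, D, F}.

**Document vectors** (`corpus`, `vectorize`). Abstracts are split by a
rule-based splitter (terminal `.?!` + whitespace + uppercase/digit start,
with an abbreviation guard covering single initials, "et al.", "i.e.",
"Fig." and similar); it is deterministic and dependency-free, which matters
more here than handling every edge case of scientific prose. Location
weights default to MeSH = 3, title = 2, sentence-with-entity = 2,
sentence-without = 1: curated MeSH indexing is the strongest evidence, title
co-occurrence next, plain abstract text weakest. All four are configurable;
setting them equal reproduces the no-weight-matrix ablation. The combined
vector is normalized to unit sum; the default applies log(1+v) first
(natural log — the base cancels in ratios only if applied uniformly, so one
base is fixed globally). `sum1` (no transform) reproduces the standardized
normalization ablation; the log variant damps the over-weighting of short
documents. Note the log transform is deliberately *not* invariant to uniform
weight scaling; the raw combination is homogeneous of degree 1, and the
sum1-normalized vector is scale-invariant.

**Term weights** (`weighting`). IDF = sqrt(1/Σw) is computed over the
**normalized** document vectors (the declared product of the vectorization
stage), separately for the gene-assigned and disease-assigned vector sets by
default (a keyword's importance differs between the two aspects;
`idf_scope="joint"` pools them). Keywords never observed in a scope have no
TW there: IDF is undefined at Σw = 0, and such keywords would contribute
nothing anyway.

**Profiles and scores** (`profiles`, `association`). A profile is the
keyword-wise sum over the entity's document vectors, scaled by TW. Entities
with no retained documents keep an **empty profile**, and pairs involving one
score 0 with a `degenerate` flag rather than being dropped — this keeps the
association table a full cross-product and evaluation denominators
well-defined. The cross-product cosine is computed with row-normalized sparse
matrices; a per-pair dict-based `cosine` provides the reference path used in
tests.

**Evaluation** (`evaluation`). P(x) and R(x) use an **inclusive** threshold
(score ≥ x), exactly as the formulas state; ties at x are counted. Precision
at an empty denominator is reported as missing (NaN, written `NA`), never 0
or 1. The PR sweep defaults to a 0.00–1.00 grid in steps of 0.01 and is
reported raw, without interpolation.

## Synthetic studies

The generator (`simulate`) emulates the statistical structure the method
exploits, not real language. A complete b-ary keyword tree (depth 6,
branching 3, five categories by default — 1815 keywords, 405+ at depth ≥ 5)
stands in for MeSH. Each entity receives a signature of `signature_size`
keywords; each known pair shares `floor(theta * signature_size)` of them,
allocated from a disjoint pool so unrelated entities overlap only through
noise. Documents plant the signature where the pipeline looks: two signature
keywords in the title, three as MeSH terms, and sentence slots filled with
signature keywords except at `noise_rate`, with the entity co-mentioned per
sentence at `co_mention_prob`. Signatures are drawn from depth ≥ 5 nodes so
the PWK penalty does not confound recovery tests; `n_confounders` plants
shallow generic keywords in every document to exercise the PWK ablation, and
`signal_in_sentences=False` confines signal to titles/MeSH for the
weight-matrix ablation. Entity names are synthetic tokens absent from the
keyword vocabulary, so entity and keyword matching never collide.

Default study conditions — 50 genes, 20 diseases, 30 known pairs, signature
size 10, overlap 0.8, noise 0.1, 5 documents per entity, 4 sentences per
document — are the package's standard benchmark and what
`scripts/acceptance.py` runs. At this size a full run takes well under a
second, and five replicate seeds give stable top-|K| precision.

What passing these tests shows: the implementation recovers planted
co-occurrence signal, ranks it above chance overlap, responds to the
ablations in the expected direction, and is bit-deterministic. What it does
not show: performance on real PubMed text, where synonymy, ambiguous gene
symbols, uneven document counts and correlated topics are the dominant
difficulties; none of those are modeled here.

## Numerical and design choices

- Keyword and entity matching normalizes to lowercase with collapsed
  whitespace; tokens are maximal alphanumeric runs, so punctuation and
  hyphens act as boundaries.
- Unit-sum checks use an absolute tolerance of 1e-9; cosine oracle
  comparisons 1e-12. Cross-product scores are clipped to [0, 1] to absorb
  floating-point overshoot at the 1e-16 level.
- Ranking ties (equal cosine) break deterministically by (gene_id,
  disease_id) wherever a top-k cut is taken.
- Score binning uses half-open bins with a closed last bin, so a score of
  exactly 1.0 is counted.
- All generator randomness flows from one `numpy` Generator seeded
  explicitly; document order, keyword draws and therefore all downstream
  scores are reproducible bit-for-bit from (config, seed).
- The library surface is organized around `GeneDiseaseModel.fit()` returning
  a `GeneDiseaseResults`; the stage functions remain public for users who
  want a single step.

## Known limitations

- Table-style location weights are reduced to four scalars; users who want a
  finer weighting can pass any non-negative `WeightConfig` but not a full
  per-location × per-co-occurrence grid.
- No synonym (entry-term) expansion of MeSH descriptors and no stemming:
  "neoplasm" does not match "neoplasms".
- IDF over normalized vectors means a keyword's Σw depends on what else each
  document mentions; this is intended (it measures share of attention, not
  raw frequency) but differs from classical document-count IDF.
- The sentence splitter's abbreviation guard is a fixed list; unusual
  abbreviations will over-split. Splitting errors only move weight between
  the with/without co-mention sentence classes.
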