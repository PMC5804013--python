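"""Corpus-level term weights: TW = IDF x PWK.

IDF here is a frequency-of-weight variant, sqrt(1 / sum_w), where sum_w is a
keyword's total weighted value over all document vectors in scope -- keywords
spread over many vectors get small IDF. PWK (see :mod:`meshmine.mesh`)
additionally penalizes keywords near the MeSH root. IDF scopes are kept
separate for gene-assigned and disease-assigned document vectors by default,
since a keyword's importance differs between the two aspects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .mesh import Dictionary, pwk
from .vectorize import DocVector


@dataclass
class CorpusStats:
    """sum_w: keyword -> total weighted value across in-scope doc vectors."""

    sum_w: dict[str, float]
    scope: str = "joint"  # {genes, diseases, joint}


@dataclass
class TermWeights:
    """Final keyword weights tw[k] = idf(sum_w[k]) * pwk(depth(k))."""

    tw: dict[str, float]
    scope: str = "joint"

    def __getitem__(self, keyword: str) -> float:
        return self.tw[keyword]

    def get(self, keyword: str, default: float = 0.0) -> float:
        return self.tw.get(keyword, default)

    def __len__(self) -> int:
        return len(self.tw)


def corpus_sums(doc_vectors: Iterable[DocVector], scope: str = "joint") -> CorpusStats:
    """Accumulate per-keyword totals over a collection of document vectors."""
    sum_w: dict[str, float] = {}
    for vec in doc_vectors:
        for kw, v in vec.entries.items():
            sum_w[kw] = sum_w.get(kw, 0.0) + v
    return CorpusStats({k: v for k, v in sum_w.items() if v > 0}, scope=scope)


def idf(sum_w_value: float) -> float:
    """sqrt(1 / sum_w): strictly decreasing in the keyword's total weight."""
    if sum_w_value <= 0:
        raise ValueError(f"sum_w must be positive, got {sum_w_value}")
    return math.sqrt(1.0 / sum_w_value)


def term_weights(stats: CorpusStats, dictionary: Dictionary, use_pwk: bool = True) -> TermWeights:
    """TW per keyword; ``use_pwk=False`` drops the depth penalty (ablation).

    Keywords never observed in the scope get no TW (IDF is undefined at
    sum_w = 0) and contribute nothing to that scope's entity vectors.
    """
    tw: dict[str, float] = {}
    for kw, sw in stats.sum_w.items():
        if kw not in dictionary:
            raise KeyError(f"keyword {kw!r} in corpus stats is missing from the dictionary")
        penalty = pwk(dictionary.keyword_depth[kw]) if use_pwk else 1.0
        tw[kw] = idf(sw) * penalty
    return TermWeights(tw, scope=stats.scope)


def write_term_weights(
    stats: CorpusStats, weights: TermWeights, dictionary: Dictionary, path: Union[str, Path]
) -> None:
    """Serialize ``keyword / sum_w / idf / pwk / tw`` as TSV for inspection."""
    lines = ["keyword\tsum_w\tidf\tpwk\ttw\n"]
    for kw in sorted(weights.tw):
        sw = stats.sum_w[kw]
        p = pwk(dictionary.keyword_depth[kw])
        lines.append(f"{kw}\t{sw:.10g}\t{idf(sw):.10g}\t{p:.10g}\t{weights.tw[kw]:.10g}\n")
    Path(path).write_text("".join(lines), encoding="utf-8")
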