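"""Precision/recall evaluation against a gold-standard linkage set.

With K the set of known gene-disease pairs and a cosine threshold x:

    P(x) = |{pairs with cosine >= x} intersect K| / |{pairs with cosine >= x}|
    R(x) = |{pairs with cosine >= x} intersect K| / |K|

The threshold is inclusive. P(x) is undefined (reported as NaN, written as
``NA``) when no pair reaches x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GoldStandard:
    """Set of known (gene_id, disease_id) linkages."""

    known: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.known)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GoldStandard":
        return cls(frozenset((str(g), str(d)) for g, d in pairs))

    @classmethod
    def from_tsv(cls, path: Union[str, Path, IO[str]]) -> "GoldStandard":
        """Read ``gene_id<TAB>disease_id`` lines; ``#`` comments."""
        handle = open(path, encoding="utf-8") if not hasattr(path, "read") else path
        pairs = []
        try:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"malformed gold-standard record at line {lineno}: {line!r}")
                pairs.append((parts[0], parts[1]))
        finally:
            if handle is not path:
                handle.close()
        return cls.from_pairs(pairs)

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = [f"{g}\t{d}\n" for g, d in sorted(self.known)]
        Path(path).write_text("".join(lines), encoding="utf-8")


def _check_threshold(x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {x}")


def precision_at(table: pd.DataFrame, gold: GoldStandard, x: float) -> float:
    """P(x); NaN when no pair scores >= x."""
    _check_threshold(x)
    above = table["cosine"].to_numpy() >= x
    n_above = int(above.sum())
    if n_above == 0:
        return math.nan
    known = table["is_known"].to_numpy()
    return float((above & known).sum()) / n_above


def recall_at(table: pd.DataFrame, gold: GoldStandard, x: float) -> float:
    """R(x); requires a non-empty gold standard."""
    _check_threshold(x)
    if len(gold) == 0:
        raise ValueError("gold standard is empty; recall is undefined")
    above = table["cosine"].to_numpy() >= x
    known = table["is_known"].to_numpy()
    return float((above & known).sum()) / len(gold)


def pr_curve(
    table: pd.DataFrame,
    gold: GoldStandard,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """One (threshold, precision, recall, n_above) row per threshold.

    Default grid: 0.00..1.00 in steps of 0.01.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0, 101) / 100.0, 2)
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly ascending")
    scores = table["cosine"].to_numpy()
    known = table["is_known"].to_numpy()
    n_known = len(gold)
    if n_known == 0:
        raise ValueError("gold standard is empty; recall is undefined")
    rows = []
    for x in thresholds:
        _check_threshold(x)
        above = scores >= x
        n_above = int(above.sum())
        tp = int((above & known).sum())
        rows.append(
            {
                "threshold": x,
                "precision": tp / n_above if n_above else math.nan,
                "recall": tp / n_known,
                "n_above": n_above,
            }
        )
    return pd.DataFrame(rows)


def precision_in_ranges(
    table: pd.DataFrame, gold: GoldStandard, edges: Sequence[float]
) -> pd.DataFrame:
    """Known-pair fraction within each half-open score range [e_i, e_{i+1}).

    The last range is closed on the right; empty ranges report NaN.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("range edges must be strictly ascending")
    scores = table["cosine"].to_numpy()
    known = table["is_known"].to_numpy()
    rows = []
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        last = i == len(edges) - 2
        mask = (scores >= lo) & ((scores <= hi) if last else (scores < hi))
        n = int(mask.sum())
        rows.append(
            {
                "lo": lo,
                "hi": hi,
                "n_pairs": n,
                "known_fraction": float((mask & known).sum()) / n if n else math.nan,
            }
        )
    return pd.DataFrame(rows)


def precision_at_rank(table: pd.DataFrame, k: int) -> float:
    """Known-pair fraction among the k highest-scoring pairs.

    Ties are broken deterministically by (gene_id, disease_id) so the value
    is reproducible across runs.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    top = table.sort_values(
        ["cosine", "gene_id", "disease_id"], ascending=[False, True, True]
    ).head(k)
    return float(top["is_known"].sum()) / k


def write_pr_curve(curve: pd.DataFrame, path: Union[str, Path]) -> None:
    """TSV ``threshold / precision / recall / n_above``; NaN printed as NA."""
    curve.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
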