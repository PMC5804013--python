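"""Gene-disease scoring: cosine similarity over the full lexicon cross-product.

Profiles are non-negative, so cosine scores live in [0, 1]. Pairs where
either profile is empty score 0 and are flagged degenerate rather than
dropped, keeping evaluation denominators well-defined over the full
cross-product.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import sparse

from .evaluation import GoldStandard
from .profiles import EntityProfile

#: Default bin edges for the score-distribution summary.
DEFAULT_BIN_EDGES = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)


def cosine(v1: Mapping[str, float], v2: Mapping[str, float]) -> float:
    """(v1 . v2) / (|v1| |v2|); 0 if either vector is empty or all-zero."""
    if any(v < 0 for v in v1.values()) or any(v < 0 for v in v2.values()):
        raise ValueError("profile vectors must be non-negative")
    n1 = math.sqrt(sum(v * v for v in v1.values()))
    n2 = math.sqrt(sum(v * v for v in v2.values()))
    if n1 == 0 or n2 == 0:
        return 0.0
    dot = sum(v * v2[k] for k, v in v1.items() if k in v2)
    return dot / (n1 * n2)


def _profile_matrix(
    profiles: Sequence[EntityProfile], kw_index: Mapping[str, int]
) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for i, prof in enumerate(profiles):
        for kw, v in prof.vec.items():
            if v < 0:
                raise ValueError(f"negative profile entry for {prof.entity_id!r}/{kw!r}")
            rows.append(i)
            cols.append(kw_index[kw])
            vals.append(v)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(profiles), max(len(kw_index), 1)), dtype=np.float64
    )


def score_all(
    gene_profiles: Mapping[str, EntityProfile],
    disease_profiles: Mapping[str, EntityProfile],
    gold: Optional[GoldStandard] = None,
) -> pd.DataFrame:
    """Score every (gene, disease) pair; rows ordered by gene_id, disease_id.

    Returns a DataFrame with columns gene_id, disease_id, cosine, is_known,
    degenerate. A gold-standard pair naming an entity absent from the
    profiles raises.
    """
    gene_ids = sorted(gene_profiles)
    disease_ids = sorted(disease_profiles)
    if gold is not None:
        for g, d in sorted(gold.known):
            if g not in gene_profiles:
                raise KeyError(f"gold-standard gene {g!r} not in the gene lexicon")
            if d not in disease_profiles:
                raise KeyError(f"gold-standard disease {d!r} not in the disease lexicon")

    keywords = sorted(
        {kw for p in gene_profiles.values() for kw in p.vec}
        | {kw for p in disease_profiles.values() for kw in p.vec}
    )
    kw_index = {kw: i for i, kw in enumerate(keywords)}
    G = _profile_matrix([gene_profiles[g] for g in gene_ids], kw_index)
    D = _profile_matrix([disease_profiles[d] for d in disease_ids], kw_index)

    def row_normalize(m: sparse.csr_matrix) -> sparse.csr_matrix:
        norms = np.sqrt(np.asarray(m.multiply(m).sum(axis=1)).ravel())
        inv = np.zeros_like(norms)
        nz = norms > 0
        inv[nz] = 1.0 / norms[nz]
        return sparse.diags(inv) @ m

    scores = np.asarray((row_normalize(G) @ row_normalize(D).T).todense())
    np.clip(scores, 0.0, 1.0, out=scores)
    gene_empty = np.array([len(gene_profiles[g].vec) == 0 for g in gene_ids])
    disease_empty = np.array([len(disease_profiles[d].vec) == 0 for d in disease_ids])
    degenerate = gene_empty[:, None] | disease_empty[None, :]

    known = gold.known if gold is not None else frozenset()
    n_g, n_d = len(gene_ids), len(disease_ids)
    table = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, n_d),
            "disease_id": np.tile(disease_ids, n_g),
            "cosine": scores.ravel(),
            "is_known": [
                (g, d) in known for g in gene_ids for d in disease_ids
            ],
            "degenerate": degenerate.ravel(),
        }
    )
    return table


def bin_distribution(
    table: pd.DataFrame, edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Bin scores into half-open [e_i, e_{i+1}) bins; the last bin is closed.

    Returns per-bin counts and proportions (summing to 1).
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly ascending")
    counts, _ = np.histogram(table["cosine"].to_numpy(), bins=edges)
    total = counts.sum()
    return pd.DataFrame(
        {
            "lo": edges[:-1],
            "hi": edges[1:],
            "count": counts,
            "proportion": counts / total if total else np.zeros(len(counts)),
        }
    )


def write_association_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """TSV with cosine printed to 6 decimals."""
    out = table.copy()
    out["cosine"] = out["cosine"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_association_table(path: Union[str, Path]) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "disease_id": str})
    table["cosine"] = table["cosine"].astype(float)
    table["is_known"] = table["is_known"].astype(bool)
    table["degenerate"] = table["degenerate"].astype(bool)
    return table
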