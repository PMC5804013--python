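"""Model/Results facade over the scoring pipeline.

`GeneDiseaseModel` is constructed from data (corpus records, a MeSH
dictionary, gene/disease lexicons and optionally a gold standard) plus the
method options; `fit()` estimates the corpus-level term weights, builds the
entity profiles and scores every pair, returning a `GeneDiseaseResults`
object that carries the association table, the evaluation sweep and a
`summary()` report.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .association import bin_distribution, write_association_table
from .corpus import EntityLexicon, RawRecord, read_corpus
from .evaluation import GoldStandard, precision_at_rank, write_pr_curve
from .mesh import Dictionary, parse_mesh
from .pipeline import PipelineOptions, PipelineResult, run_pipeline


class GeneDiseaseModel:
    """Literature-mining association model over a corpus and two lexicons."""

    def __init__(
        self,
        records: Iterable[RawRecord],
        dictionary: Dictionary,
        gene_lexicon: EntityLexicon,
        disease_lexicon: EntityLexicon,
        gold: Optional[GoldStandard] = None,
        options: Optional[PipelineOptions] = None,
    ):
        self.records = list(records)
        self.dictionary = dictionary
        self.gene_lexicon = gene_lexicon
        self.disease_lexicon = disease_lexicon
        self.gold = gold
        self.options = options or PipelineOptions()

    @classmethod
    def from_files(
        cls,
        corpus_path: Union[str, Path],
        dictionary_path: Union[str, Path],
        gene_lexicon_path: Union[str, Path],
        disease_lexicon_path: Union[str, Path],
        gold_path: Optional[Union[str, Path]] = None,
        corpus_format: str = "jsonl",
        dictionary_format: str = "tabular",
        options: Optional[PipelineOptions] = None,
    ) -> "GeneDiseaseModel":
        return cls(
            records=read_corpus(corpus_path, format=corpus_format),
            dictionary=parse_mesh(dictionary_path, format=dictionary_format),
            gene_lexicon=EntityLexicon.from_tsv(gene_lexicon_path),
            disease_lexicon=EntityLexicon.from_tsv(disease_lexicon_path),
            gold=GoldStandard.from_tsv(gold_path) if gold_path else None,
            options=options,
        )

    def fit(self) -> "GeneDiseaseResults":
        result = run_pipeline(
            self.records,
            self.dictionary,
            self.gene_lexicon,
            self.disease_lexicon,
            gold=self.gold,
            options=self.options,
        )
        return GeneDiseaseResults(self, result)


class GeneDiseaseResults:
    """Fitted results: association table, PR sweep, and reports."""

    def __init__(self, model: GeneDiseaseModel, pipeline_result: PipelineResult):
        self.model = model
        self._result = pipeline_result

    @property
    def associations(self) -> pd.DataFrame:
        return self._result.table

    @property
    def pr_curve(self) -> Optional[pd.DataFrame]:
        return self._result.curve

    @property
    def gene_profiles(self):
        return self._result.gene_profiles

    @property
    def disease_profiles(self):
        return self._result.disease_profiles

    @property
    def term_weights(self) -> tuple:
        return self._result.gene_tw, self._result.disease_tw

    def bin_distribution(self, edges=None) -> pd.DataFrame:
        if edges is None:
            return self._result.bins
        return bin_distribution(self._result.table, edges)

    def top_pairs(self, k: int = 10) -> pd.DataFrame:
        return self._result.table.sort_values(
            ["cosine", "gene_id", "disease_id"], ascending=[False, True, True]
        ).head(k).reset_index(drop=True)

    def save(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_association_table(self._result.table, outdir / "associations.tsv")
        if self._result.curve is not None:
            write_pr_curve(self._result.curve, outdir / "pr_curve.tsv")
        self._result.bins.to_csv(outdir / "bins.tsv", sep="\t", index=False)

    def summary(self) -> str:
        """Plain-text report of corpus coverage, score mass and P/R landmarks."""
        r = self._result
        table = r.table
        lines = [
            "Gene-disease association by MeSH-keyword profile similarity",
            "=" * 60,
            f"documents retained        {len(r.corpus.documents):>10d}",
            f"gene profiles             {len(r.gene_profiles):>10d}"
            f"  (non-empty {sum(1 for p in r.gene_profiles.values() if len(p)):d})",
            f"disease profiles          {len(r.disease_profiles):>10d}"
            f"  (non-empty {sum(1 for p in r.disease_profiles.values() if len(p)):d})",
            f"scored pairs              {len(table):>10d}",
            f"degenerate pairs          {int(table['degenerate'].sum()):>10d}",
            "",
            "cosine distribution",
        ]
        for row in r.bins.itertuples():
            lines.append(f"  [{row.lo:.2f}, {row.hi:.2f}{']' if row.hi == r.bins['hi'].iloc[-1] else ')'}"
                         f"  {row.count:>8d}  {row.proportion:7.2%}")
        if r.curve is not None and self.model.gold is not None:
            k = len(self.model.gold)
            lines += [
                "",
                f"gold-standard pairs       {k:>10d}",
                f"precision of top-{k} pairs  {precision_at_rank(table, k):.3f}",
                "threshold  precision  recall",
            ]
            for x in (0.0, 0.1, 0.3, 0.5, 0.7, 0.9):
                row = r.curve[r.curve["threshold"].round(6) == x]
                if len(row):
                    p = row["precision"].iloc[0]
                    p_str = f"{p:9.3f}" if p == p else "       NA"
                    lines.append(f"   {x:5.2f}   {p_str}  {row['recall'].iloc[0]:6.3f}")
        return "\n".join(lines)
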