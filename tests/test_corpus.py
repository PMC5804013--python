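"""Record ingestion, sentence splitting, keyword/entity matching, filtering."""

import io
import random

import pytest

from meshmine.corpus import (
    EntityLexicon,
    RawRecord,
    build_corpus,
    match_entities,
    match_keywords,
    read_corpus,
    split_sentences,
)
from meshmine.mesh import Dictionary, TreePosition

MEDLINE_XML = """\
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>101</PMID>
      <Article>
        <ArticleTitle>BRCA1 in breast neoplasms</ArticleTitle>
        <Abstract>
          <AbstractText>First part.</AbstractText>
          <AbstractText>Second part.</AbstractText>
        </Abstract>
      </Article>
      <MeshHeadingList>
        <MeshHeading><DescriptorName>Breast Neoplasms</DescriptorName></MeshHeading>
      </MeshHeadingList>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


def make_dict(*keywords: str) -> Dictionary:
    return Dictionary({kw: frozenset({TreePosition("C04.100")}) for kw in keywords})


class TestReadCorpus:
    def test_medline_xml_roundtrip(self):
        (rec,) = list(read_corpus(io.StringIO(MEDLINE_XML), format="medline_xml"))
        assert rec == RawRecord("101", "BRCA1 in breast neoplasms", "First part. Second part.", ("Breast Neoplasms",))

    def test_jsonl_roundtrip_and_missing_abstract(self):
        lines = (
            '{"id": "a", "title": "T", "abstract": "Abs.", "mesh": ["M"]}\n'
            '{"id": "b", "title": "U"}\n'
        )
        recs = list(read_corpus(io.StringIO(lines), format="jsonl"))
        assert recs[0] == RawRecord("a", "T", "Abs.", ("M",))
        assert recs[1].abstract == ""

    def test_duplicate_doc_id_skipped(self):
        lines = "".join(f'{{"id": "{i}", "title": "t"}}\n' for i in ("a", "b", "a"))
        assert len(list(read_corpus(io.StringIO(lines), format="jsonl"))) == 2

    def test_malformed_record_reports_position(self):
        with pytest.raises(ValueError, match="position 1"):
            list(read_corpus(io.StringIO('{"id": "a", "title": "t"}\nnot json\n'), format="jsonl"))


class TestSplitSentences:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("", []),
            ("A result. Another result.", ["A result.", "Another result."]),
            ("E. coli causes disease.", ["E. coli causes disease."]),
            ("Seen in Fig. 2 and et al. reports.", ["Seen in Fig. 2 and et al. reports."]),
            ("Really? Yes! Sure.", ["Really?", "Yes!", "Sure."]),
            ("lowercase continuation. not split here", ["lowercase continuation. not split here"]),
        ],
    )
    def test_rule_based_splitting(self, text, expected):
        assert split_sentences(text) == expected

    def test_content_is_preserved_and_no_empty_sentences(self):
        text = "One sentence. Two sentences! A third? Done."
        parts = split_sentences(text)
        assert all(parts)
        assert "".join(parts).replace(" ", "") == text.replace(" ", "")


class TestMatchKeywords:
    def test_longest_match_is_preferred_and_non_overlapping(self):
        d = make_dict("neoplasms", "lung neoplasms")
        assert dict(match_keywords("neoplasms of the lung", d)) == {"neoplasms": 1}
        assert dict(match_keywords("lung neoplasms and neoplasms", d)) == {
            "lung neoplasms": 1,
            "neoplasms": 1,
        }

    def test_empty_text_and_case_insensitivity(self):
        d = make_dict("dna")
        assert dict(match_keywords("", d)) == {}
        assert dict(match_keywords("DNA and dna and DnA", d)) == {"dna": 3}

    def test_matches_on_token_boundaries_only(self):
        d = make_dict("lung")
        assert dict(match_keywords("lungfish have lungs, not a lung", d)) == {"lung": 1}

    def test_equivalence_with_bruteforce_scan_oracle(self):
        """Greedy longest-match counting equals an independent re-scan on random texts."""
        rng = random.Random(20240901)
        vocab = ["alpha", "beta", "gamma", "delta", "eps"]
        phrases = ["alpha", "beta", "alpha beta", "gamma delta", "beta gamma alpha", "delta", "eps",
                   "gamma", "alpha beta gamma", "eps alpha"]
        d = make_dict(*phrases)
        phrase_tokens = sorted((tuple(p.split()) for p in phrases), key=len, reverse=True)
        for _ in range(100):
            tokens = [rng.choice(vocab) for _ in range(30)]
            # oracle: explicit position scan, longest candidate first
            expected: dict[str, int] = {}
            i = 0
            while i < len(tokens):
                for cand in phrase_tokens:
                    if tuple(tokens[i : i + len(cand)]) == cand:
                        key = " ".join(cand)
                        expected[key] = expected.get(key, 0) + 1
                        i += len(cand)
                        break
                else:
                    i += 1
            assert dict(match_keywords(" ".join(tokens), d)) == expected


class TestMatchEntities:
    def test_mention_sites_across_fields(self):
        lex = EntityLexicon({"g1": frozenset({"BRCA1"}), "g2": frozenset({"TP53", "p53"})})
        mentions = match_entities(
            title="BRCA1 study",
            sentences=["TP53 acts here.", "Nothing.", "We saw p53 and TP53."],
            mesh_terms=["BRCA1 protein"],
            lexicon=lex,
        )
        assert mentions["g1"] == {("title", None), ("mesh", None)}
        assert mentions["g2"] == {("sentence", 0), ("sentence", 2)}

    def test_synonyms_collapse_to_one_site_entry(self):
        lex = EntityLexicon({"g": frozenset({"TP53", "p53"})})
        mentions = match_entities("", ["p53 binds TP53."], [], lex)
        assert mentions == {"g": {("sentence", 0)}}


class TestBuildCorpus:
    def test_keeps_only_entity_linked_documents(self, toy_records, toy_gene_lexicon, toy_disease_lexicon):
        corpus = build_corpus(toy_records, toy_gene_lexicon, toy_disease_lexicon)
        assert set(corpus.documents) == {"d1", "d2"}  # botany paper dropped
        assert corpus.gene_index["g:brca1"] == ["d1"]
        assert corpus.gene_index["g:tp53"] == []
        assert corpus.disease_index["dis:breast"] == ["d1"]
        assert corpus.disease_index["dis:lung"] == ["d2"]

    def test_document_serving_gene_and_disease_is_indexed_twice(self, toy_records, toy_gene_lexicon, toy_disease_lexicon):
        corpus = build_corpus(toy_records, toy_gene_lexicon, toy_disease_lexicon)
        doc = corpus.documents["d1"]
        assert "g:brca1" in doc.gene_mentions and "dis:breast" in doc.disease_mentions

    def test_empty_lexicons_empty_corpus(self, toy_records):
        lex = EntityLexicon({"x": frozenset({"zzzz"})})
        lex2 = EntityLexicon({"y": frozenset({"qqqq"})})
        corpus = build_corpus(toy_records, lex, lex2)
        assert len(corpus) == 0

    def test_overlapping_lexicon_ids_rejected(self, toy_records, toy_gene_lexicon):
        with pytest.raises(ValueError, match="share ids"):
            build_corpus(toy_records, toy_gene_lexicon, EntityLexicon({"g:brca1": frozenset({"x"})}))

    def test_filtering_never_grows_and_allcovering_lexicon_keeps_all(self, toy_records, toy_gene_lexicon):
        covering = EntityLexicon(
            {
                "d:any1": frozenset({"neoplasms", "overview", "botany"}),
            }
        )
        corpus = build_corpus(toy_records, toy_gene_lexicon, covering)
        assert len(corpus) == len(toy_records)

    def test_deterministic_across_passes(self, toy_records, toy_gene_lexicon, toy_disease_lexicon):
        c1 = build_corpus(toy_records, toy_gene_lexicon, toy_disease_lexicon)
        c2 = build_corpus(toy_records, toy_gene_lexicon, toy_disease_lexicon)
        assert set(c1.documents) == set(c2.documents)
        assert c1.gene_index == c2.gene_index
        assert c1.disease_index == c2.disease_index


class TestEntityLexicon:
    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("g1\tBRCA1|brca-1\ng2\tTP53\n", encoding="utf-8")
        lex = EntityLexicon.from_tsv(p)
        assert lex.names["g1"] == frozenset({"brca1", "brca-1"})
        out = tmp_path / "round.tsv"
        lex.to_tsv(out)
        assert EntityLexicon.from_tsv(out).names == lex.names

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("g1\ta\ng1\tb\n", encoding="utf-8")
        with pytest.raises(ValueError, match="duplicate"):
            EntityLexicon.from_tsv(p)
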