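import io

import pytest

from meshmine import Dictionary, EntityLexicon, GoldStandard, parse_mesh
from meshmine.corpus import RawRecord

TOY_DICT_TABULAR = """\
# toy dictionary
neoplasms\tC04
lung neoplasms\tC04.588.894
breast neoplasms\tC04.588.180
family\tF01.829.263
lung\tA04.411
dna\tD13.444
mutation\tG05.365.590
"""


@pytest.fixture
def toy_dictionary() -> Dictionary:
    return parse_mesh(io.StringIO(TOY_DICT_TABULAR), format="tabular")


@pytest.fixture
def toy_records() -> list[RawRecord]:
    return [
        RawRecord(
            "d1",
            "BRCA1 and breast neoplasms",
            "Mutation of BRCA1 raises risk. The lung is not involved.",
            ("Breast Neoplasms", "Family"),
        ),
        RawRecord(
            "d2",
            "Lung neoplasms overview",
            "Carcinoma affects the lung. Carcinoma spreads.",
            ("Lung Neoplasms",),
        ),
        RawRecord("d3", "Unrelated botany paper", "Plants grow in soil.", ()),
    ]


@pytest.fixture
def toy_gene_lexicon() -> EntityLexicon:
    return EntityLexicon({"g:brca1": frozenset({"BRCA1"}), "g:tp53": frozenset({"TP53", "p53"})})


@pytest.fixture
def toy_disease_lexicon() -> EntityLexicon:
    return EntityLexicon(
        {
            "dis:breast": frozenset({"breast neoplasms"}),
            "dis:lung": frozenset({"lung neoplasms", "carcinoma"}),
        }
    )


@pytest.fixture
def toy_gold() -> GoldStandard:
    return GoldStandard.from_pairs([("g:brca1", "dis:breast")])
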