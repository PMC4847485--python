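import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from weakext.corpus import Article, CuratedRecord, TermDictionary
from weakext.extraction import extract_passages, match_mentions


@pytest.fixture
def diabetes_article() -> Article:
    return Article(
        doc_id="doc1",
        title="Genome-wide association study of type 2 diabetes",
        abstract="Patients with type 2 diabetes were examined in a large cohort.",
        sections=[
            ("Methods", ["A total of 4500 German participants were recruited "
                         "in the discovery stage of the study."]),
            ("Results", ["Variants showed association with diabetes. "
                         "Previous work linked these loci to obesity."]),
        ],
    )


@pytest.fixture
def phenotype_dict() -> TermDictionary:
    return TermDictionary(
        entries={
            "type 2 diabetes": "Type 2 diabetes",
            "type-2 diabetes": "Type 2 diabetes",
            "diabetes": "Type 2 diabetes",
            "obesity": "Obesity",
        },
        name="phenotypes",
    )


@pytest.fixture
def ethnicity_dict() -> TermDictionary:
    return TermDictionary(
        entries={
            "german": "European",
            "germans": "European",
            "european": "European",
            "japanese": "East Asian",
            "han chinese": "East Asian",
            "african american": "African American",
            "african-american": "African American",
        },
        name="ethnicities",
    )


@pytest.fixture
def phenotype_record() -> CuratedRecord:
    return CuratedRecord("doc1", "phenotype",
                         phenotype_terms=["Type-2 Diabetes", "Obesity"])


@pytest.fixture
def stage_record() -> CuratedRecord:
    return CuratedRecord(
        "doc1", "stage_ethnicity",
        tuples=frozenset({("initial", "European"),
                          ("replication", "East Asian")}))


@pytest.fixture
def diabetes_passages(diabetes_article, phenotype_dict):
    mentions = match_mentions(diabetes_article, phenotype_dict)
    return extract_passages(mentions, diabetes_article, "cross_sentence")
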