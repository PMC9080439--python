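"""Shared fixtures: recorded-style E-utilities responses and small corpora.

The XML payloads are synthetic stand-ins shaped like real ESearch/EFetch
responses, so the retrieval client is exercised entirely offline.
"""

import pytest

from amrtriage import (
    EmbeddingParams,
    Lexicon,
    RawDocument,
    SyntheticSpec,
    generate_corpus,
    tokenize_corpus,
    train_pvdm,
)

ESEARCH_RESPONSE = b"""<?xml version="1.0"?>
<eSearchResult>
  <Count>3</Count><RetMax>3</RetMax><RetStart>0</RetStart>
  <IdList>
    <Id>9000001</Id>
    <Id>9000002</Id>
    <Id>9000003</Id>
  </IdList>
</eSearchResult>
"""

ESEARCH_EMPTY = b"""<?xml version="1.0"?>
<eSearchResult><Count>0</Count><IdList></IdList></eSearchResult>
"""


def jats_article(pmcid_digits: str, title: str, paragraphs: list[str]) -> str:
    body = "".join(f"<p>{p}</p>" for p in paragraphs)
    return (
        "<article>"
        "<front><article-meta>"
        f'<article-id pub-id-type="pmc">{pmcid_digits}</article-id>'
        f"<title-group><article-title>{title}</article-title></title-group>"
        "<abstract><p>Abstract of the study.</p></abstract>"
        "</article-meta></front>"
        f"<body>{body}</body>"
        "</article>"
    )


EFETCH_TWO_ARTICLES = (
    '<?xml version="1.0"?><pmc-articleset>'
    + jats_article("9000001", "Efflux pumps in resistant bacteria",
                   ["Antibiotic efflux drives resistance.", "Second paragraph."])
    + jats_article("9000002", "Plasmid-borne beta-lactamases",
                   ["Beta-lactamase genes spread on plasmids."])
    + "</pmc-articleset>"
).encode()


@pytest.fixture
def esearch_transport():
    def transport(url: str) -> bytes:
        return ESEARCH_RESPONSE
    return transport


@pytest.fixture
def efetch_transport():
    def transport(url: str) -> bytes:
        return EFETCH_TWO_ARTICLES
    return transport


@pytest.fixture
def tiny_lexicon() -> Lexicon:
    return Lexicon.from_terms(
        ["antibiotic efflux", "beta-lactamase", "resistance gene", "plasmid"],
        source_tag="test fixture",
    )


@pytest.fixture
def tiny_corpus(tiny_lexicon) -> list[RawDocument]:
    return [
        RawDocument("PMC1", "t1", "Efflux pumps drive antibiotic efflux in bacteria."),
        RawDocument("PMC2", "t2", "The beta-lactamase enzyme confers resistance."),
        RawDocument("PMC3", "t3", "Plasmid transfer moves a resistance gene between cells."),
    ]


#: compact generator settings for unit tests that need a trained model quickly
SMALL_SPEC = SyntheticSpec(
    n_relevant=15, n_irrelevant=15, lexicon_size=20, background_vocab_size=100,
    doc_length_mean=60, seed=7,
)
SMALL_PARAMS = EmbeddingParams(vector_size=50, epochs=10, min_count=1, seed=7)


@pytest.fixture(scope="session")
def small_trained():
    """One small synthetic corpus with a trained PV-DM model, shared per session."""
    documents, gold, lexicon = generate_corpus(SMALL_SPEC)
    tokenized = tokenize_corpus(documents, lexicon)
    model = train_pvdm(tokenized, SMALL_PARAMS)
    return {
        "documents": documents,
        "gold": gold,
        "lexicon": lexicon,
        "tokenized": tokenized,
        "model": model,
    }
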