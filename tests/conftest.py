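import pytest

from bifactor.corpus import (
    Biobank,
    CitationEdge,
    Corpus,
    Document,
    FundingCategoryRecord,
    FEATURE_NAMES,
    Mention,
)
from bifactor.synthetic import GeneratorConfig, generate_corpus


def make_features(value: float = 0.0) -> dict:
    return {f: value for f in FEATURE_NAMES}


def make_biobank(bid: str, **kw) -> Biobank:
    defaults = dict(
        id=bid,
        name=f"Bank {bid}",
        establishment_year=2000,
        host_institution="inst_A",
        host_country="US",
        reference_paper_ids=[],
        pi_ids=["p1"],
        team_ids=["p1", "t1", "t2"],
        features=make_features(),
    )
    defaults.update(kw)
    return Biobank(**defaults)


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two biobanks, six documents, four mentions; fully valid."""
    docs = [
        Document("d1", "publication", 2010, ["a1", "a2"], [("inst_A", "US")],
                 [("cond_flu", "infectious diseases")], ["clinical research"]),
        Document("d2", "publication", 2012, ["a3"], [("inst_B", "GB")],
                 [("cond_cvd", "cardiovascular diseases")], []),
        Document("d3", "grant", 2011),
        Document("d4", "patent", 2013),
        Document("d5", "publication", 2015, ["p1", "a4"], [("inst_A", "US")]),
        Document("d6", "publication", 2016, ["a5"], [("inst_C", "DE")]),
    ]
    mentions = [
        Mention("d1", "bbA", "title"),
        Mention("d2", "bbA", "abstract"),
        Mention("d3", "bbB", "abstract"),
        Mention("d5", "bbB", "acknowledgments"),
    ]
    citations = [CitationEdge("d6", "d1"), CitationEdge("d6", "d2"),
                 CitationEdge("d5", "d1")]
    banks = [
        make_biobank("bbA", reference_paper_ids=["d1"]),
        make_biobank("bbB", host_institution="inst_B", host_country="GB",
                     establishment_year=2005),
    ]
    funding = [FundingCategoryRecord("cancer", 5e9),
               FundingCategoryRecord("aging", 2e9)]
    return Corpus(documents=docs, mentions=mentions, citations=citations,
                  biobanks=banks, funding=funding, reference_year=2024)


def small_config(**kw) -> GeneratorConfig:
    defaults = dict(n_biobanks=10, mean_mentions_per_biobank=12,
                    mention_scale=0.8, seed=0)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def synth_medium():
    """One medium synthetic corpus shared across read-only tests."""
    cfg = GeneratorConfig(n_biobanks=60, mean_mentions_per_biobank=40,
                          hidden_citation_rate=0.3, home_bias=0.7, seed=11)
    return generate_corpus(cfg)
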