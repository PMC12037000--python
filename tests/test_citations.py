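import numpy as np
import pandas as pd
import pytest

from bifactor.citations import (
    NoReferencePapers,
    coauthorship_stats,
    hidden_citation_rate,
    hidden_citation_table,
    locality_shares,
    pooled_hidden_rate,
    quintile_compare,
    rewiring_null_test,
    scientific_reach,
)
from bifactor.corpus import CitationEdge, Corpus, Document, Mention
from bifactor.impact import rank_biobanks
from bifactor.synthetic import GeneratorConfig, generate_corpus

from conftest import make_biobank


def _hidden_corpus(n_mentioning: int, n_hidden: int):
    """One biobank with one reference paper and a known hidden count."""
    docs = [Document("ref1", "publication", 2000)]
    mentions, citations = [], []
    for i in range(n_mentioning):
        pid = f"m{i}"
        docs.append(Document(pid, "publication", 2010))
        mentions.append(Mention(pid, "B"))
        if i >= n_hidden:
            citations.append(CitationEdge(pid, "ref1"))
    banks = [make_biobank("B", reference_paper_ids=["ref1"]), make_biobank("C")]
    return Corpus(documents=docs, mentions=mentions, citations=citations,
                  biobanks=banks, reference_year=2024)


class TestHiddenCitations:
    def test_all_cite_reference_gives_rate_zero(self):
        r = hidden_citation_rate(_hidden_corpus(8, 0), "B")
        assert r.hidden_rate == 0.0

    def test_none_cite_reference_gives_rate_one(self):
        r = hidden_citation_rate(_hidden_corpus(8, 8), "B")
        assert r.hidden_rate == 1.0

    def test_four_of_ten_hidden(self):
        r = hidden_citation_rate(_hidden_corpus(10, 4), "B")
        assert r.hidden_rate == pytest.approx(0.4)
        assert r.n_hidden + r.n_citing_reference == r.n_mentioning

    def test_no_reference_papers_is_excluded_not_zero(self):
        c = _hidden_corpus(5, 2)
        c.mentions.append(Mention("m0", "C"))
        c.invalidate_caches()
        with pytest.raises(NoReferencePapers):
            hidden_citation_rate(c, "C")
        assert "C" not in hidden_citation_table(c).index

    def test_hidden_plus_citing_partition_holds_on_synthetic(self, synth_medium):
        corpus, _ = synth_medium
        tab = hidden_citation_table(corpus)
        assert (tab["n_hidden"] + tab["n_citing_reference"]
                == tab["n_mentioning"]).all()
        assert tab["hidden_rate"].between(0, 1).all()


class TestScientificReach:
    def test_no_citations_means_zero_reach(self):
        c = _hidden_corpus(3, 3)
        assert scientific_reach(c, "B") == 0

    def test_same_citer_counted_once(self):
        c = _hidden_corpus(2, 2)
        c.documents.append(Document("x1", "publication", 2020))
        c.citations += [CitationEdge("x1", "m0"), CitationEdge("x1", "m1")]
        c.invalidate_caches()
        assert scientific_reach(c, "B") == 1

    def test_reach_equals_brute_force_union(self, synth_medium):
        corpus, _ = synth_medium
        for bank in corpus.biobanks[:10]:
            pubs = {d.id for d in
                    corpus.mentioning_documents(bank.id, ("publication",))}
            union = {e.citing_id for e in corpus.citations if e.cited_id in pubs}
            assert scientific_reach(corpus, bank.id) == len(union)

    def test_reach_at_least_max_single_paper_citers(self, synth_medium):
        corpus, _ = synth_medium
        bank = corpus.biobanks[0]
        pubs = {d.id for d in
                corpus.mentioning_documents(bank.id, ("publication",))}
        per_paper = {}
        for e in corpus.citations:
            if e.cited_id in pubs:
                per_paper.setdefault(e.cited_id, set()).add(e.citing_id)
        best = max((len(v) for v in per_paper.values()), default=0)
        assert scientific_reach(corpus, bank.id) >= best


class TestLocality:
    def _loc_corpus(self, affiliations_per_pub):
        docs = [Document(f"m{i}", "publication", 2010, affiliations=affs)
                for i, affs in enumerate(affiliations_per_pub)]
        mentions = [Mention(d.id, "B") for d in docs]
        banks = [make_biobank("B", host_institution="inst_A", host_country="US"),
                 make_biobank("C")]
        return Corpus(documents=docs, mentions=mentions, biobanks=banks,
                      reference_year=2024)

    def test_all_host_institution(self):
        c = self._loc_corpus([[("inst_A", "US")]] * 4)
        r = locality_shares(c, "B")
        assert (r.national_share, r.institutional_share) == (1.0, 1.0)

    def test_none_from_host_country(self):
        c = self._loc_corpus([[("inst_X", "DE")], [("inst_Y", "FR")]])
        r = locality_shares(c, "B")
        assert (r.national_share, r.institutional_share) == (0.0, 0.0)

    def test_any_author_rule(self):
        c = self._loc_corpus([[("inst_X", "DE"), ("inst_A", "US")],
                              [("inst_Z", "US")]])
        r = locality_shares(c, "B")
        assert r.national_share == 1.0
        assert r.institutional_share == 0.5

    def test_missing_affiliations_undefined(self):
        c = self._loc_corpus([[]])
        with pytest.raises(ValueError):
            locality_shares(c, "B")

    def test_home_bias_recovered(self):
        cfg = GeneratorConfig(n_biobanks=30, mean_mentions_per_biobank=30,
                              home_bias=0.7, seed=29)
        corpus, _ = generate_corpus(cfg)
        pubs = [d for d in corpus.documents
                if d.doc_type == "publication" and d.affiliations]
        shares = []
        n_total = 0
        for b in corpus.biobanks:
            try:
                r = locality_shares(corpus, b.id)
            except ValueError:
                continue
            shares.append(r.national_share * r.n_papers)
            n_total += r.n_papers
        pooled = sum(shares) / n_total
        se = np.sqrt(0.7 * 0.3 / n_total)
        assert abs(pooled - 0.7) < 4 * se


class TestRewiringNull:
    def test_determinism_under_seed(self, synth_medium):
        corpus, _ = synth_medium
        r1 = rewiring_null_test(corpus, "national", n_iter=50, seed=3)
        r2 = rewiring_null_test(corpus, "national", n_iter=50, seed=3)
        assert np.array_equal(r1.null, r2.null) and r1.p_value == r2.p_value

    def test_p_value_bounds(self, synth_medium):
        corpus, _ = synth_medium
        r = rewiring_null_test(corpus, "institutional", n_iter=99, seed=1)
        assert 1 / 100 <= r.p_value <= 1.0

    def test_strong_home_bias_is_significant(self):
        cfg = GeneratorConfig(n_biobanks=20, mean_mentions_per_biobank=15,
                              home_bias=0.9, seed=41)
        corpus, _ = generate_corpus(cfg)
        r = rewiring_null_test(corpus, "national", n_iter=199, seed=5)
        assert r.p_value < 0.05

    def test_bad_iteration_count(self, synth_medium):
        corpus, _ = synth_medium
        with pytest.raises(ValueError):
            rewiring_null_test(corpus, "national", n_iter=0, seed=1)


class TestCoauthorship:
    def _coauth_corpus(self, author_lists):
        docs = [Document(f"m{i}", "publication", 2010, author_ids=a)
                for i, a in enumerate(author_lists)]
        mentions = [Mention(d.id, "B") for d in docs]
        banks = [make_biobank("B", pi_ids=["p1"], team_ids=["p1", "t1", "t2"]),
                 make_biobank("C")]
        return Corpus(documents=docs, mentions=mentions, biobanks=banks,
                      reference_year=2024)

    def test_no_roster_overlap_gives_zero_shares(self):
        c = self._coauth_corpus([["a1"], ["a2", "a3"]])
        r = coauthorship_stats(c, "B")
        assert r.team_share == r.pi_share == r.non_pi_without_pi_share == 0.0

    def test_every_paper_with_pi(self):
        c = self._coauth_corpus([["p1", "a1"], ["p1"]])
        r = coauthorship_stats(c, "B")
        assert r.pi_share == r.team_share == 1.0
        assert r.non_pi_without_pi_count == 0

    def test_non_pi_without_pi_counted(self):
        c = self._coauth_corpus([["t1", "a1"], ["p1", "t1"], ["a2"], ["t2"]])
        r = coauthorship_stats(c, "B")
        assert r.team_share == pytest.approx(3 / 4)
        assert r.pi_share == pytest.approx(1 / 4)
        assert r.non_pi_without_pi_count == 2

    def test_pi_share_never_exceeds_team_share(self, synth_medium):
        corpus, _ = synth_medium
        for b in corpus.biobanks:
            try:
                r = coauthorship_stats(corpus, b.id)
            except ValueError:
                continue
            assert r.pi_share <= r.team_share

    def test_matches_brute_force_membership_scan(self, synth_medium):
        corpus, _ = synth_medium
        bank = corpus.biobanks[3]
        pubs = corpus.mentioning_documents(bank.id, ("publication",))
        team, pis = set(bank.team_ids), set(bank.pi_ids)
        n_team = sum(1 for d in pubs if set(d.author_ids) & team)
        n_pi = sum(1 for d in pubs if set(d.author_ids) & pis)
        r = coauthorship_stats(corpus, bank.id)
        assert r.team_share == pytest.approx(n_team / len(pubs))
        assert r.pi_share == pytest.approx(n_pi / len(pubs))

    def test_coauthorship_share_recovers_planted_mixture(self):
        cfg = GeneratorConfig(n_biobanks=40, mean_mentions_per_biobank=40,
                              seed=43)
        corpus, truth = generate_corpus(cfg)
        for b in corpus.biobanks:
            planted = truth.per_biobank[b.id]["coauthor_prob"]
            try:
                r = coauthorship_stats(corpus, b.id)
            except ValueError:
                continue
            if r.n_mentioning < 20:
                continue
            se = np.sqrt(max(planted * (1 - planted), 0.01) / r.n_mentioning)
            assert abs(r.team_share - planted) < 5 * se


class TestQuintileCompare:
    def _scores(self, n):
        return pd.DataFrame({
            "name": [f"b{i}" for i in range(n)],
            "bIF": np.linspace(1, -1, n),
        }, index=pd.Index([f"bb{i}" for i in range(n)], name="biobank_id"))

    def test_group_size_arithmetic(self):
        scores = self._scores(100)
        metric = pd.Series(np.arange(100, dtype=float), index=scores.index)
        r = quintile_compare(scores, metric)
        assert r.n_per_group == 20

    def test_identical_metric_gives_p_near_one(self):
        scores = self._scores(50)
        metric = pd.Series(5.0, index=scores.index)
        r = quintile_compare(scores, metric)
        assert r.top_mean == r.bottom_mean
        assert r.p_value > 0.99

    def test_three_sd_separation_is_significant(self):
        rng = np.random.default_rng(47)
        scores = self._scores(250)
        metric = pd.Series(rng.normal(0, 1, 250), index=scores.index)
        metric.iloc[:50] += 3.0  # top group planted 3 SD higher
        r = quintile_compare(scores, metric)
        assert r.p_value < 0.001
        assert r.top_mean > r.bottom_mean

    def test_too_few_biobanks(self):
        scores = self._scores(4)
        with pytest.raises(ValueError):
            quintile_compare(scores, pd.Series(1.0, index=scores.index))


def test_pooled_hidden_rate_matches_table(synth_medium):
    corpus, _ = synth_medium
    tab = hidden_citation_table(corpus)
    assert pooled_hidden_rate(corpus) == pytest.approx(
        tab["n_hidden"].sum() / tab["n_mentioning"].sum())


def test_quintile_compare_on_scored_corpus(synth_medium):
    corpus, _ = synth_medium
    table = rank_biobanks(corpus, min_publications=1)
    metric = pd.Series({b.id: locality_shares(corpus, b.id).national_share
                        for b in corpus.biobanks
                        if b.id in table.index})
    r = quintile_compare(table, metric)
    assert 0.0 <= r.top_mean <= 1.0 and 0.0 <= r.bottom_mean <= 1.0
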