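"""Hidden citations, scientific reach, locality, and coauthorship access.

A *hidden citation* is a publication that mentions a biobank (in its
title, abstract or acknowledgments) but cites none of the biobank's
official reference papers — uncredited use invisible to citation counts.
*Scientific reach* is the number of unique articles citing the
publications that mention a biobank.  Locality asks what share of a
biobank's mentioning publications carry an author affiliated with the
host country or host institution, and whether that share exceeds a null
model in which mention assignments are randomly rewired while preserving
each biobank's mention count.  Coauthorship statistics measure the
"coauthorship for access" practice: the share of mentioning papers that
list a biobank team member or PI among their authors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus


class NoReferencePapers(ValueError):
    """Biobank has no reference papers: excluded from hidden-citation
    analysis (distinct from a zero rate)."""


@dataclass
class HiddenCitationResult:
    biobank_id: str
    n_mentioning: int
    n_hidden: int
    n_citing_reference: int
    reach: int

    @property
    def hidden_rate(self) -> float:
        return self.n_hidden / self.n_mentioning


@dataclass
class LocalityResult:
    biobank_id: str
    national_share: float
    institutional_share: float
    n_papers: int


@dataclass
class CoauthorshipResult:
    biobank_id: str
    n_mentioning: int
    team_share: float
    pi_share: float
    non_pi_without_pi_count: int
    non_pi_without_pi_share: float


def _cited_sets(c: Corpus) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for e in c.citations:
        out.setdefault(e.citing_id, set()).add(e.cited_id)
    return out


def hidden_citation_rate(c: Corpus, biobank_id: str) -> HiddenCitationResult:
    """Hidden-citation counts for one biobank (publications only).

    Raises :class:`NoReferencePapers` when the biobank has no designated
    reference papers — it cannot be assessed, which is not a rate of 0.
    """
    bank = c.bank_index[biobank_id]
    refs = set(bank.reference_paper_ids)
    if not refs:
        raise NoReferencePapers(biobank_id)
    pubs = c.mentioning_documents(biobank_id, doc_types=("publication",))
    if not pubs:
        raise ValueError(f"{biobank_id} has no mentioning publications")
    cited = _cited_sets(c)
    n_hidden = sum(1 for d in pubs if not (cited.get(d.id, set()) & refs))
    return HiddenCitationResult(
        biobank_id=biobank_id,
        n_mentioning=len(pubs),
        n_hidden=n_hidden,
        n_citing_reference=len(pubs) - n_hidden,
        reach=scientific_reach(c, biobank_id),
    )


def scientific_reach(c: Corpus, biobank_id: str) -> int:
    """Number of unique documents citing any publication mentioning the biobank."""
    pub_ids = {d.id for d in c.mentioning_documents(biobank_id, ("publication",))}
    citers = {e.citing_id for e in c.citations if e.cited_id in pub_ids}
    return len(citers)


def locality_shares(c: Corpus, biobank_id: str) -> LocalityResult:
    """National and institutional shares of mentioning publications.

    A publication is national (institutional) if *any* author affiliation
    matches the host country (host institution).  Shares are over
    mentioning publications with at least one affiliation; raises if none
    has affiliations.
    """
    bank = c.bank_index[biobank_id]
    pubs = [d for d in c.mentioning_documents(biobank_id, ("publication",))
            if d.affiliations]
    if not pubs:
        raise ValueError(f"{biobank_id}: no mentioning publication has affiliations")
    nat = sum(1 for d in pubs
              if any(country == bank.host_country for _i, country in d.affiliations))
    inst = sum(1 for d in pubs
               if any(i == bank.host_institution for i, _c in d.affiliations))
    return LocalityResult(biobank_id, nat / len(pubs), inst / len(pubs), len(pubs))


def mean_national_share(c: Corpus) -> float:
    """Unweighted mean national share over biobanks with assessable papers."""
    vals = []
    for b in c.biobanks:
        try:
            vals.append(locality_shares(c, b.id).national_share)
        except ValueError:
            continue
    if not vals:
        raise ValueError("no biobank has mentioning publications with affiliations")
    return float(np.mean(vals))


@dataclass
class RewiringNullResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_iter: int


def rewiring_null_test(
    c: Corpus,
    statistic: str | Callable[[np.ndarray, np.ndarray], float] = "national",
    n_iter: int = 1000,
    seed: int | None = None,
) -> RewiringNullResult:
    """Permutation test of a locality statistic against a rewired null.

    The null randomly reassigns biobank labels over mention slots — a
    degree-preserving rewiring of the bipartite mention graph that keeps
    each biobank's mention count and each document's mention slots fixed
    (asserted every iteration).  ``statistic`` is ``"national"``,
    ``"institutional"`` (mean share over biobanks) or a callable
    ``f(match_matrix, assignment) -> float`` over the slot match matrix.
    The empirical p-value uses the +1 correction
    ``p = (1 + #{null >= observed}) / (1 + n_iter)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(c.biobanks) < 2:
        raise ValueError("rewiring null needs >= 2 biobanks")
    rng = np.random.default_rng(seed)

    banks = [b.id for b in c.biobanks]
    bank_idx = {b: i for i, b in enumerate(banks)}
    docs = c.doc_index

    # mention slots over publications with affiliations
    slot_doc: list[str] = []
    slot_bank = []
    for m in c.mentions:
        d = docs.get(m.document_id)
        if d is not None and d.doc_type == "publication" and d.affiliations:
            slot_doc.append(m.document_id)
            slot_bank.append(bank_idx[m.biobank_id])
    if not slot_doc:
        raise ValueError("no mention slots with affiliations")
    assignment = np.asarray(slot_bank, dtype=np.intp)
    n_banks = len(banks)

    # match[s, b]: does slot s's document have an affiliation matching bank b
    if statistic in ("national", "institutional"):
        if statistic == "national":
            keys = [{country for _i, country in docs[did].affiliations}
                    for did in slot_doc]
            bank_key = [c.bank_index[b].host_country for b in banks]
        else:
            keys = [{inst for inst, _c in docs[did].affiliations}
                    for did in slot_doc]
            bank_key = [c.bank_index[b].host_institution for b in banks]
        match = np.zeros((len(slot_doc), n_banks), dtype=bool)
        for j, bk in enumerate(bank_key):
            match[:, j] = [bk in k for k in keys]

        def stat_fn(m: np.ndarray, a: np.ndarray) -> float:
            hits = m[np.arange(len(a)), a]
            per_bank_hits = np.bincount(a, weights=hits, minlength=n_banks)
            per_bank_n = np.bincount(a, minlength=n_banks)
            mask = per_bank_n > 0
            return float((per_bank_hits[mask] / per_bank_n[mask]).mean())
    else:
        match = np.zeros((len(slot_doc), n_banks), dtype=bool)
        stat_fn = statistic  # type: ignore[assignment]

    observed = stat_fn(match, assignment)
    expected_counts = np.bincount(assignment, minlength=n_banks)
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(assignment)
        counts = np.bincount(perm, minlength=n_banks)
        assert np.array_equal(counts, expected_counts), "rewiring broke mention counts"
        null[i] = stat_fn(match, perm)
    p = (1 + int((null >= observed).sum())) / (1 + n_iter)
    return RewiringNullResult(observed=observed, null=null, p_value=p, n_iter=n_iter)


def coauthorship_stats(c: Corpus, biobank_id: str) -> CoauthorshipResult:
    """Team/PI coauthorship shares over a biobank's mentioning publications."""
    bank = c.bank_index[biobank_id]
    team, pis = set(bank.team_ids), set(bank.pi_ids)
    if not team:
        raise ValueError(f"{biobank_id} has an empty team roster")
    pubs = c.mentioning_documents(biobank_id, doc_types=("publication",))
    if not pubs:
        raise ValueError(f"{biobank_id} has no mentioning publications")
    n = len(pubs)
    n_team = n_pi = n_nonpi_only = 0
    for d in pubs:
        authors = set(d.author_ids)
        has_pi = bool(authors & pis)
        has_team = bool(authors & team)
        n_team += has_team
        n_pi += has_pi
        n_nonpi_only += has_team and not has_pi
    return CoauthorshipResult(
        biobank_id=biobank_id,
        n_mentioning=n,
        team_share=n_team / n,
        pi_share=n_pi / n,
        non_pi_without_pi_count=n_nonpi_only,
        non_pi_without_pi_share=n_nonpi_only / n,
    )


@dataclass
class QuintileComparison:
    top_mean: float
    bottom_mean: float
    top_ci: tuple[float, float]
    bottom_ci: tuple[float, float]
    t_statistic: float
    p_value: float
    n_per_group: int


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    m = values.mean()
    if len(values) < 2 or values.std(ddof=1) == 0:
        return (float(m), float(m))
    se = values.std(ddof=1) / np.sqrt(len(values))
    half = stats.t.ppf(0.5 + level / 2, df=len(values) - 1) * se
    return (float(m - half), float(m + half))


def quintile_compare(scores: pd.DataFrame, metric: pd.Series) -> QuintileComparison:
    """Welch t-test of a metric between top- and bottom-bIF quintiles.

    ``scores`` is a bIF table indexed by biobank id (as returned by
    :func:`bifactor.impact.rank_biobanks`); ``metric`` is aligned on the
    same index.  Group size is ``n // 5``.
    """
    if len(scores) < 5:
        raise ValueError("quintile comparison needs >= 5 scored biobanks")
    ordered = scores.sort_values(["bIF", "name"], ascending=[False, True],
                                 kind="mergesort").index
    k = len(ordered) // 5
    if k < 2:
        raise ValueError("fewer than 2 biobanks per quintile group")
    top = metric.reindex(ordered[:k]).dropna().to_numpy(dtype=float)
    bottom = metric.reindex(ordered[-k:]).dropna().to_numpy(dtype=float)
    if len(top) < 2 or len(bottom) < 2:
        raise ValueError("fewer than 2 metric values per group")
    if top.std(ddof=1) == 0 and bottom.std(ddof=1) == 0:
        t_stat, p = (0.0, 1.0) if top.mean() == bottom.mean() else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_ind(top, bottom, equal_var=False)
    return QuintileComparison(
        top_mean=float(top.mean()),
        bottom_mean=float(bottom.mean()),
        top_ci=_mean_ci(top),
        bottom_ci=_mean_ci(bottom),
        t_statistic=float(t_stat),
        p_value=float(p),
        n_per_group=k,
    )


def hidden_citation_table(c: Corpus) -> pd.DataFrame:
    """Hidden-citation results for every assessable biobank."""
    rows = []
    for b in c.biobanks:
        try:
            r = hidden_citation_rate(c, b.id)
        except (NoReferencePapers, ValueError):
            continue
        rows.append({
            "biobank_id": r.biobank_id, "n_mentioning": r.n_mentioning,
            "n_hidden": r.n_hidden, "n_citing_reference": r.n_citing_reference,
            "hidden_rate": r.hidden_rate, "reach": r.reach,
        })
    return pd.DataFrame(rows).set_index("biobank_id") if rows else pd.DataFrame()


def pooled_hidden_rate(c: Corpus) -> float:
    """Corpus-level hidden-citation rate: total hidden / total mentioning."""
    tab = hidden_citation_table(c)
    if tab.empty:
        raise ValueError("no assessable biobanks")
    return float(tab["n_hidden"].sum() / tab["n_mentioning"].sum())
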