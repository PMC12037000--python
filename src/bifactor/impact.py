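"""Biobank Impact Factor: research impact R, disease impact D, and bIF.

The score combines two components.  Research impact standardizes a
biobank's mention counts within the scored cohort, per document type::

    R = sum_i clip((r_i - mu_i) / sigma_i, -1, 1),   i over the 5 types,

so R lies in [-5, 5]; a type with zero cohort variance contributes 0.
Disease impact sums three cohort-standardized, clipped components —
scope (number of distinct conditions studied), depth (mean share of each
condition's literature attributable to the biobank) and rare-disease
share — giving D in [-3, 3].  The final score is age-normalized::

    bIF = (0.9 * R + 0.1 * D) / Y,

with Y the biobank's age in years (floored at 1), so Y * bIF lies in
[-4.8, 4.8]; 4.8 = 0.9*5 + 0.1*3 is the score of a biobank saturating
every component.  A positive bIF indicates above-cohort-average impact.

Standardization uses the sample (n-1) standard deviation over the scored
cohort, which by default is the set of biobanks with at least 20
mentioning publications.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, DOC_TYPES

DEFAULT_WEIGHTS = (0.9, 0.1)
DEFAULT_MIN_PUBLICATIONS = 20


def standardize_clip(values: np.ndarray) -> np.ndarray:
    """Cohort z-score clipped to [-1, 1]; all-zero if the SD vanishes.

    Uses the sample (ddof=1) standard deviation, so at least two values
    are required.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("standardization requires at least 2 biobanks")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros_like(values)
    return np.clip((values - values.mean()) / sd, -1.0, 1.0)


def mention_count_matrix(c: Corpus, eligible: Iterable[str]) -> pd.DataFrame:
    """Distinct-document mention counts, one row per biobank, one column
    per document type."""
    eligible = list(eligible)
    if not eligible:
        raise ValueError("eligible biobank set is empty")
    counts = pd.DataFrame(0, index=pd.Index(eligible, name="biobank_id"),
                          columns=list(DOC_TYPES), dtype=int)
    elig = set(eligible)
    docs = c.doc_index
    seen: set[tuple[str, str]] = set()
    for m in c.mentions:
        if m.biobank_id not in elig:
            continue
        key = (m.document_id, m.biobank_id)
        if key in seen:
            continue
        seen.add(key)
        d = docs.get(m.document_id)
        if d is not None:
            counts.loc[m.biobank_id, d.doc_type] += 1
    return counts


def research_impact(M: pd.DataFrame) -> pd.Series:
    """R per biobank from a mention-count matrix (rows standardized per type)."""
    if len(M) < 2:
        raise ValueError("research impact needs >= 2 biobanks (cohort SD undefined)")
    z = np.column_stack([standardize_clip(M[t].to_numpy()) for t in DOC_TYPES])
    return pd.Series(z.sum(axis=1), index=M.index, name="R")


def z_matrix(M: pd.DataFrame) -> pd.DataFrame:
    """Per-type standardized clipped scores (the addends of R)."""
    if len(M) < 2:
        raise ValueError("research impact needs >= 2 biobanks (cohort SD undefined)")
    return pd.DataFrame(
        {t: standardize_clip(M[t].to_numpy()) for t in DOC_TYPES}, index=M.index
    )


def disease_impact_raw(
    c: Corpus, eligible: Sequence[str], rare_condition_ids: Iterable[str]
) -> pd.DataFrame:
    """Unstandardized scope/depth/rare components per biobank.

    scope_raw: distinct conditions on the biobank's mentioning publications.
    depth_raw: mean over those conditions of the biobank's share of all
    corpus publications tagged with the condition.
    rare_raw: the biobank's share of all corpus publications tagged with
    at least one rare condition.
    """
    rare = set(rare_condition_ids)
    # corpus-wide per-condition publication counts (all publications)
    cond_total: dict[str, int] = {}
    rare_total = 0
    for d in c.documents:
        if d.doc_type != "publication" or not d.mesh_conditions:
            continue
        conds = {cond for cond, _cat in d.mesh_conditions}
        for cond in conds:
            cond_total[cond] = cond_total.get(cond, 0) + 1
        if conds & rare:
            rare_total += 1

    rows = []
    for bid in eligible:
        pubs = c.mentioning_documents(bid, doc_types=("publication",))
        bank_cond: dict[str, int] = {}
        bank_rare = 0
        for d in pubs:
            conds = {cond for cond, _cat in d.mesh_conditions}
            for cond in conds:
                bank_cond[cond] = bank_cond.get(cond, 0) + 1
            if conds & rare:
                bank_rare += 1
        scope = float(len(bank_cond))
        if bank_cond:
            depth = float(np.mean([bank_cond[k] / cond_total[k] for k in bank_cond]))
        else:
            depth = 0.0
        rare_share = bank_rare / rare_total if rare_total > 0 else 0.0
        rows.append((bid, scope, depth, rare_share))
    return pd.DataFrame(rows, columns=["biobank_id", "scope_raw", "depth_raw", "rare_raw"]
                        ).set_index("biobank_id")


def disease_impact(
    c: Corpus, eligible: Sequence[str], rare_condition_ids: Iterable[str]
) -> pd.DataFrame:
    """Standardized disease components and their sum D in [-3, 3]."""
    rare = set(rare_condition_ids)
    if not rare:
        warnings.warn("empty rare-condition set: Drare is 0 for all biobanks",
                      stacklevel=2)
    raw = disease_impact_raw(c, eligible, rare)
    out = pd.DataFrame(index=raw.index)
    out["Dscope"] = standardize_clip(raw["scope_raw"].to_numpy())
    out["Ddepth"] = standardize_clip(raw["depth_raw"].to_numpy())
    out["Drare"] = (standardize_clip(raw["rare_raw"].to_numpy())
                    if rare else np.zeros(len(raw)))
    out["D"] = out[["Dscope", "Ddepth", "Drare"]].sum(axis=1)
    return out


def compute_bif(R, D, Y, weights: tuple[float, float] = DEFAULT_WEIGHTS):
    """Age-normalized weighted impact score (w_R * R + w_D * D) / Y.

    Accepts scalars or aligned arrays; every age must be >= 1 year.
    """
    Y_arr = np.asarray(Y, dtype=float)
    if np.any(Y_arr < 1):
        raise ValueError("biobank age Y must be >= 1")
    w_r, w_d = weights
    result = (w_r * np.asarray(R, dtype=float) + w_d * np.asarray(D, dtype=float)) / Y_arr
    if np.isscalar(R) and np.isscalar(D) and np.isscalar(Y):
        return float(result)
    return result


def rank_biobanks(
    c: Corpus,
    min_publications: int = DEFAULT_MIN_PUBLICATIONS,
    rare_condition_ids: Iterable[str] = (),
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Score every biobank passing the publication cutoff; sort by bIF.

    The cutoff set is also the standardization cohort for both R and D.
    Ties in bIF are broken lexicographically by biobank name.  Returns a
    table with per-type counts ``n_<type>``, per-type scores ``z_<type>``,
    R, the disease components, age Y and bIF.
    """
    elig = sorted(
        b.id for b in c.biobanks
        if len(c.mentioning_documents(b.id, doc_types=("publication",))) >= min_publications
    )
    if not elig:
        raise ValueError(f"no biobank has >= {min_publications} mentioning publications")
    if len(elig) < 2:
        raise ValueError("scoring cohort must contain >= 2 biobanks")

    M = mention_count_matrix(c, elig)
    Z = z_matrix(M)
    R = Z.sum(axis=1)
    Dtab = disease_impact(c, elig, rare_condition_ids)

    banks = c.bank_index
    names = pd.Series({bid: banks[bid].name for bid in elig})
    Y = pd.Series({bid: max(1, c.reference_year - banks[bid].establishment_year)
                   for bid in elig})

    table = pd.DataFrame(index=pd.Index(elig, name="biobank_id"))
    table["name"] = names
    for t in DOC_TYPES:
        table[f"n_{t}"] = M[t]
    for t in DOC_TYPES:
        table[f"z_{t}"] = Z[t]
    table["R"] = R
    table[["Dscope", "Ddepth", "Drare", "D"]] = Dtab
    table["Y"] = Y
    table["bIF"] = compute_bif(R.to_numpy(), Dtab["D"].to_numpy(), Y.to_numpy(),
                               weights=weights)
    return table.sort_values(["bIF", "name"], ascending=[False, True],
                             kind="mergesort")
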