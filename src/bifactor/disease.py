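"""Disease profiles and funding–research alignment.

Maps each biobank to the disease categories of its mentioning
publications (multi-label: a publication tagged with several conditions
counts once toward each), and quantifies how well publication output per
funding category tracks the available funding by ordinary least squares.
Over- or under-representation of a category is the regression residual
expressed as a percentage of the expected publication count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus import Corpus, FundingCategoryRecord

GENERAL_PURPOSE_LABEL = "general-purpose"


def disease_profile(c: Corpus, biobank_id: str) -> dict:
    """Condition and category publication counts for one biobank."""
    cond_counts: dict[str, int] = {}
    cat_counts: dict[str, int] = {}
    for d in c.mentioning_documents(biobank_id, doc_types=("publication",)):
        seen_cond = set()
        seen_cat = set()
        for cond, cat in d.mesh_conditions:
            if cond not in seen_cond:
                seen_cond.add(cond)
                cond_counts[cond] = cond_counts.get(cond, 0) + 1
            if cat not in seen_cat:
                seen_cat.add(cat)
                cat_counts[cat] = cat_counts.get(cat, 0) + 1
    return {"biobank_id": biobank_id, "condition_counts": cond_counts,
            "category_counts": cat_counts}


def principal_category(c: Corpus, biobank_id: str) -> str:
    """Disease category with the most publications; lexicographic tie-break.

    A biobank with no disease-tagged mentioning publication is labelled
    general-purpose.
    """
    cat_counts = disease_profile(c, biobank_id)["category_counts"]
    if not cat_counts:
        return GENERAL_PURPOSE_LABEL
    return min(cat_counts, key=lambda k: (-cat_counts[k], k))


def category_shares(c: Corpus, biobank_ids=None) -> pd.Series:
    """Share of disease-tagged publications per category (multi-label).

    Denominator is the number of disease-tagged mentioning publications
    (or all disease-tagged publications when ``biobank_ids`` is None).
    """
    if biobank_ids is None:
        pubs = [d for d in c.documents
                if d.doc_type == "publication" and d.mesh_conditions]
    else:
        seen = set()
        pubs = []
        for bid in biobank_ids:
            for d in c.mentioning_documents(bid, doc_types=("publication",)):
                if d.mesh_conditions and d.id not in seen:
                    seen.add(d.id)
                    pubs.append(d)
    counts: dict[str, int] = {}
    for d in pubs:
        for cat in {cat for _c, cat in d.mesh_conditions}:
            counts[cat] = counts.get(cat, 0) + 1
    n = len(pubs)
    if n == 0:
        return pd.Series(dtype=float)
    return pd.Series(counts).sort_index() / n


@dataclass
class FundingFit:
    slope: float
    intercept: float
    r: float
    slope_se: float
    expected: pd.Series  # per-category expected publications
    actual: pd.Series
    funding: pd.Series


def actual_publications_by_category(c: Corpus) -> pd.Series:
    """Publications per RCDC category over the whole corpus (multi-label)."""
    counts: dict[str, int] = {}
    for d in c.documents:
        if d.doc_type != "publication":
            continue
        for cat in set(d.rcdc_categories):
            counts[cat] = counts.get(cat, 0) + 1
    return pd.Series(counts, dtype=float).sort_index()


def funding_regression(
    funding: list[FundingCategoryRecord] | pd.Series,
    actual_pubs: pd.Series,
) -> FundingFit:
    """OLS of per-category publication counts on raw funding dollars.

    Returns the fit plus per-category expected publication counts; the
    Pearson r quantifies funding–output alignment.  Categories present in
    the funding table but missing from ``actual_pubs`` count as 0 papers.
    """
    if isinstance(funding, pd.Series):
        f = funding.astype(float)
    else:
        f = pd.Series({rec.rcdc_category: rec.mean_annual_funding for rec in funding})
    if len(f) < 3:
        raise ValueError("funding regression needs >= 3 categories")
    if float(f.std(ddof=0)) == 0.0:
        raise ValueError("funding has zero variance across categories")
    y = actual_pubs.reindex(f.index).fillna(0.0).astype(float)

    X = sm.add_constant(f.to_numpy())
    fit = sm.OLS(y.to_numpy(), X).fit()
    expected = pd.Series(fit.fittedvalues, index=f.index, name="expected_pubs")
    r = float(np.corrcoef(f.to_numpy(), y.to_numpy())[0, 1])
    return FundingFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r=r,
        slope_se=float(fit.bse[1]),
        expected=expected,
        actual=y,
        funding=f,
    )


def representation_residual(actual: float, expected: float) -> float:
    """Surplus (deficit) of actual over expected publications in percent.

    ``100 * (actual - expected) / expected``; positive values mark
    over-represented categories.  Unrounded; use
    :func:`representation_table` for integer-percent display.
    """
    if expected <= 0:
        raise ValueError("expected publications must be positive")
    return 100.0 * (actual - expected) / expected


def representation_table(fit: FundingFit) -> pd.DataFrame:
    """Per-category funding, actual/expected publications and surplus %.

    ``surplus_percent`` is rounded to the nearest integer for display;
    ``surplus_percent_raw`` keeps full precision.  Categories whose
    expected count is not positive get NaN surplus.
    """
    rows = []
    for cat in fit.funding.index:
        exp_v = float(fit.expected[cat])
        act_v = float(fit.actual[cat])
        if exp_v > 0:
            surplus = representation_residual(act_v, exp_v)
        else:
            surplus = np.nan
        rows.append({
            "rcdc_category": cat,
            "funding": float(fit.funding[cat]),
            "actual_pubs": act_v,
            "expected_pubs": exp_v,
            "residual": act_v - exp_v,
            "surplus_percent_raw": surplus,
            "surplus_percent": int(round(surplus)) if np.isfinite(surplus) else np.nan,
        })
    return pd.DataFrame(rows).set_index("rcdc_category")
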