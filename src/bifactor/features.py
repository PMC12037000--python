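"""Regression of impact on biobank characteristics.

Fits ``log(bIF + 1) = b0 + b1*X1 + ... + b14*X14 + e`` with Gaussian
errors over the 14 biobank features (cohort size, open-data index,
PI prestige, population/hospital base, genetic data offerings,
registries, surveys, follow-up, medical records, general-purpose flag),
reporting Bonferroni-corrected p-values (m = 14) and fit diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus import FEATURE_NAMES

N_TESTS = len(FEATURE_NAMES)
MIN_CASES = 30


class CollinearityError(ValueError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear feature columns: {', '.join(self.columns)}")


@dataclass
class FeatureModelResult:
    table: pd.DataFrame      # coef, se, ci_low, ci_high, p_raw, p_bonferroni, significant
    r_squared: float
    deviance: float
    deviance_per_df: float
    pearson_chi2: float
    pearson_chi2_per_df: float
    n_biobanks: int


def fit_feature_model(
    features: pd.DataFrame,
    bif: pd.Series,
    alpha: float = 0.05,
) -> FeatureModelResult:
    """Fit the 14-feature impact model.

    ``features`` holds one row per biobank with the 14 feature columns
    (and optionally a ``biobank_id`` column or index to align on);
    ``bif`` the matching impact scores.  Rows with ``bIF <= -1`` (log
    undefined) are dropped with a warning.  Perfectly collinear feature
    columns raise :class:`CollinearityError` naming the offending set.
    """
    df = features.copy()
    if "biobank_id" in df.columns:
        df = df.set_index("biobank_id")
    missing = [f for f in FEATURE_NAMES if f not in df.columns]
    if missing:
        raise ValueError(f"feature columns missing: {missing}")
    y = pd.Series(np.asarray(bif, dtype=float),
                  index=df.index if len(bif) == len(df) else bif.index)
    y = y.reindex(df.index)

    keep = y.notna() & df[list(FEATURE_NAMES)].notna().all(axis=1)
    n_bad = int((y[keep] <= -1).sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} biobank(s) with bIF <= -1", stacklevel=2)
        keep &= y > -1
    df, y = df[keep], y[keep]
    if len(df) < MIN_CASES:
        raise ValueError(f"need >= {MIN_CASES} complete cases, have {len(df)}")

    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        rdiag = np.abs(np.diag(np.linalg.qr(np.column_stack([np.ones(len(X)), X]))[1]))
        names = ["const", *FEATURE_NAMES]
        tol = rdiag.max() * max(X.shape) * np.finfo(float).eps
        raise CollinearityError([names[i] for i in np.where(rdiag <= tol)[0]] or
                                list(FEATURE_NAMES))

    design = sm.add_constant(X)
    response = np.log1p(y.to_numpy())
    model = sm.GLM(response, design, family=sm.families.Gaussian())
    fit = model.fit()

    ci = fit.conf_int(alpha=alpha)
    names = ["const", *FEATURE_NAMES]
    p_raw = np.asarray(fit.pvalues)
    p_bonf = np.minimum(1.0, p_raw * N_TESTS)
    p_bonf[0] = p_raw[0]  # intercept is not one of the 14 tested features
    table = pd.DataFrame({
        "coef": fit.params,
        "se": fit.bse,
        "ci_low": ci[:, 0],
        "ci_high": ci[:, 1],
        "p_raw": p_raw,
        "p_bonferroni": p_bonf,
    }, index=names)
    table["significant"] = table["p_bonferroni"] < alpha

    resid = response - fit.fittedvalues
    tss = float(((response - response.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else np.nan
    df_resid = fit.df_resid
    return FeatureModelResult(
        table=table,
        r_squared=r2,
        deviance=float(fit.deviance),
        deviance_per_df=float(fit.deviance / df_resid),
        pearson_chi2=float(fit.pearson_chi2),
        pearson_chi2_per_df=float(fit.pearson_chi2 / df_resid),
        n_biobanks=int(len(df)),
    )
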