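"""Disease co-occurrence models from binary EHR indicator tables.

For every target disease k we fit an L1-penalized (lasso) logistic
regression of its indicator on the indicators of all other diseases, with
the penalty chosen by 5-fold cross-validated deviance.  The fitted
log-odds coefficients form a directed association matrix: entry [k][i] is
the penalized log-odds of disease i in the model for disease k, and a
coefficient of exactly zero means the penalty eliminated the predictor.
A coefficient of 0.1 corresponds to an odds ratio of about 1.1
(log 1.1 ~ 0.095), the operational comorbidity cutoff used throughout.

Optional covariates (age entering through the same degree-4 B-spline
basis as the survival models, plus any other columns supplied) are
adjusted for but never reported in the association matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .hazards import _age_spline

__all__ = [
    "ComorbidityFit",
    "ConcordanceReport",
    "ComorbidSimilarReport",
    "fit_comorbidity_model",
    "association_matrix",
    "cross_cohort_concordance",
    "comorbid_given_similar",
]

DEFAULT_CS = np.logspace(-3, 1, 8)


@dataclass
class ComorbidityFit:
    """Lasso-logistic fit for one target disease."""

    target: str
    disease_coefs: pd.Series  # log-odds per other disease
    covariate_coefs: pd.Series  # retained internally, never in the matrix
    chosen_C: float
    n_cases: int


def _covariate_frame(covariates: pd.DataFrame) -> pd.DataFrame:
    parts = []
    if "age" in covariates.columns:
        spline = _age_spline(covariates["age"].to_numpy(), degree=4, n_knots=5)
        basis = spline.transform(covariates[["age"]].to_numpy(dtype=float))
        parts.append(pd.DataFrame(
            basis, columns=[f"age_bs_{i}" for i in range(basis.shape[1])],
            index=covariates.index,
        ))
    other = [c for c in covariates.columns if c != "age"]
    if other:
        parts.append(covariates[other].astype(float))
    return pd.concat(parts, axis=1)


def fit_comorbidity_model(
    ehr: pd.DataFrame,
    target: str,
    covariates: pd.DataFrame | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    Cs: np.ndarray = DEFAULT_CS,
) -> ComorbidityFit:
    """Lasso-logistic regression of one disease on all others.

    The inverse-penalty grid ``Cs`` is searched by stratified
    ``cv_folds``-fold cross-validation on the log-loss (deviance) and the
    winning penalty is refit on all subjects.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if target not in ehr.columns:
        raise KeyError(f"target disease {target!r} not in EHR table")
    y = ehr[target].to_numpy()
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == len(y):
        raise ValueError(f"target {target!r} has zero cases or zero controls")
    others = [c for c in ehr.columns if c != target]
    X = ehr[others].to_numpy(dtype=float)
    columns = list(others)
    if covariates is not None:
        cov = _covariate_frame(covariates)
        X = np.hstack([X, cov.to_numpy(dtype=float)])
        columns += list(cov.columns)

    model = LogisticRegressionCV(
        Cs=Cs,
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=1000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coefs = pd.Series(model.coef_.ravel(), index=columns)
    return ComorbidityFit(
        target=target,
        disease_coefs=coefs[others],
        covariate_coefs=coefs.drop(others),
        chosen_C=float(model.C_[0]),
        n_cases=n_cases,
    )


def association_matrix(
    ehr: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    min_cases: int = 50,
    Cs: np.ndarray = DEFAULT_CS,
) -> pd.DataFrame:
    """Directed disease x disease comorbidity coefficient matrix.

    Row k holds the coefficients of the model for disease k; the diagonal
    is NaN (a disease never predicts itself).  Diseases with fewer than
    ``min_cases`` cases (or controls) are not modeled and appear only as
    predictors.
    """
    counts = ehr.sum(axis=0)
    n = len(ehr)
    qualifying = [
        d for d in ehr.columns if min_cases <= counts[d] <= n - min_cases
    ]
    if len(qualifying) < 2:
        raise ValueError(
            f"fewer than 2 diseases reach min_cases={min_cases}"
        )
    mat = pd.DataFrame(np.nan, index=qualifying, columns=ehr.columns, dtype=float)
    for d in qualifying:
        fit = fit_comorbidity_model(
            ehr, d, covariates=covariates, cv_folds=cv_folds, seed=seed, Cs=Cs
        )
        mat.loc[d, fit.disease_coefs.index] = fit.disease_coefs
    mat = mat[qualifying]  # square, directed, NaN diagonal
    mat.index.name = "target"
    return mat


@dataclass
class ConcordanceReport:
    """Agreement of directed comorbidity coefficients across two cohorts."""

    r: float
    r2: float
    n_pairs: int
    n_concordant: int
    n_discordant: int
    assoc_threshold: float
    pairs: pd.DataFrame  # target, predictor, value_a, value_b
    discordant: pd.DataFrame = field(repr=False, default=None)


def cross_cohort_concordance(
    a: pd.DataFrame, b: pd.DataFrame, assoc_threshold: float = 0.1
) -> ConcordanceReport:
    """Pearson agreement of shared directed pairs between two matrices.

    A pair is concordant when both cohorts place it on the same side of
    ``assoc_threshold``.  R² is r² for this simple pairing.
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared diseases between the two matrices")
    rows = []
    for k in shared:
        for i in shared:
            if i == k:
                continue
            va, vb = a.loc[k, i], b.loc[k, i]
            if np.isnan(va) or np.isnan(vb):
                continue
            rows.append((k, i, float(va), float(vb)))
    pairs = pd.DataFrame(rows, columns=["target", "predictor", "value_a", "value_b"])
    if len(pairs) < 3:
        raise ValueError("need at least 3 shared directed pairs")
    r, _ = stats.pearsonr(pairs["value_a"], pairs["value_b"])
    above_a = pairs["value_a"] >= assoc_threshold
    above_b = pairs["value_b"] >= assoc_threshold
    concordant = above_a == above_b
    discordant = pairs[~concordant].reset_index(drop=True)
    return ConcordanceReport(
        r=float(r),
        r2=float(r) ** 2,
        n_pairs=len(pairs),
        n_concordant=int(concordant.sum()),
        n_discordant=int((~concordant).sum()),
        assoc_threshold=assoc_threshold,
        pairs=pairs,
        discordant=discordant,
    )


@dataclass
class ComorbidSimilarReport:
    """How often biomarker-similar disease pairs are also comorbid."""

    fraction: float | None  # None when no pair passes corr_threshold
    undefined: bool
    corr_threshold: float
    assoc_threshold: float
    concordant: pd.DataFrame  # similar and comorbid
    discordant: pd.DataFrame  # similar but not comorbid


def comorbid_given_similar(
    correlation: pd.DataFrame,
    assoc: pd.DataFrame,
    corr_threshold: float = 0.5,
    assoc_threshold: float = 0.1,
) -> ComorbidSimilarReport:
    """Fraction of biomarker-similar pairs that are comorbid.

    Unordered pairs with profile correlation >= ``corr_threshold`` count
    as comorbid when either directed coefficient >= ``assoc_threshold``.
    The defaults (0.5, 0.1) are the operational definitions used
    throughout the atlas.
    """
    shared = correlation.index.intersection(assoc.index)
    conc, disc = [], []
    for ii in range(len(shared)):
        for jj in range(ii + 1, len(shared)):
            d1, d2 = shared[ii], shared[jj]
            c = correlation.loc[d1, d2]
            if c < corr_threshold:
                continue
            strength = np.nanmax([assoc.loc[d1, d2], assoc.loc[d2, d1]])
            row = (d1, d2, float(c), float(strength))
            (conc if strength >= assoc_threshold else disc).append(row)
    cols = ["disease_a", "disease_b", "correlation", "association"]
    conc_df = pd.DataFrame(conc, columns=cols)
    disc_df = pd.DataFrame(disc, columns=cols)
    n_similar = len(conc_df) + len(disc_df)
    if n_similar == 0:
        return ComorbidSimilarReport(
            fraction=None, undefined=True, corr_threshold=corr_threshold,
            assoc_threshold=assoc_threshold, concordant=conc_df, discordant=disc_df,
        )
    return ComorbidSimilarReport(
        fraction=len(conc_df) / n_similar,
        undefined=False,
        corr_threshold=corr_threshold,
        assoc_threshold=assoc_threshold,
        concordant=conc_df,
        discordant=disc_df,
    )
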