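"""Disease-disease similarity from biomarker hazard profiles.

Similarity is computed on the biomarker-only block of the hazard matrix,
on the log-hazard-ratio scale (protective and risk effects symmetric
around 0).  Non-biomarker covariates (age spline, sex, deprivation, BMI,
smoking, blood pressure) are always dropped so that similarity cannot
arise through shared demographic structure alone; strongly sex-linked
markers can be excluded the same way.

Three views are provided: the full Pearson correlation matrix between
disease profiles, a permutation null for the chance level of profile
correlation, and a sparse partial-correlation network estimated with a
cross-validated graphical lasso (diseases as variables, biomarker
dimensions as observations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import GraphicalLasso, GraphicalLassoCV
from sklearn.model_selection import KFold

from .hazards import HazardMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationNull",
    "PartialCorrelationNetwork",
    "biomarker_submatrix",
    "disease_correlation",
    "correlation_permutation_null",
    "partial_correlation_network",
]


def biomarker_submatrix(
    hazards: HazardMatrix, exclusions: list[str] | tuple[str, ...] = ()
) -> pd.DataFrame:
    """Biomarker-only log-HR matrix: drop fixed covariates and exclusions."""
    missing = [c for c in exclusions if c not in hazards.hr.columns]
    if missing:
        raise KeyError(f"exclusions not present in hazard matrix: {missing}")
    keep = [
        c
        for c in hazards.hr.columns
        if c not in hazards.fixed_columns and c not in exclusions
    ]
    if not keep:
        raise ValueError("no biomarker columns remain after exclusions")
    return np.log(hazards.hr[keep])


def disease_correlation(submatrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between disease profiles across biomarkers.

    A constant profile has undefined correlations; its row and column are
    set to 0 (diagonal stays 1) with a warning.
    """
    if submatrix.shape[1] < 3:
        raise ValueError("need at least 3 biomarker columns for profile correlation")
    X = submatrix.to_numpy(dtype=float)
    const = np.ptp(X, axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    if const.any():
        names = list(submatrix.index[const])
        warnings.warn(f"constant profile(s) {names}: correlations set to 0")
        corr[const, :] = 0.0
        corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=submatrix.index, columns=submatrix.index)


def permute_profiles(
    submatrix: np.ndarray, rng: np.random.Generator, scheme: str = "within_row"
) -> np.ndarray:
    """Shuffle hazard profiles under the null of no biomarker identity.

    ``within_row`` (default) independently permutes each disease's row, so
    every disease keeps its set of effect magnitudes but loses which
    biomarker carries which effect.  ``global`` shuffles the whole matrix.
    ``rows`` reorders entire profiles across diseases, leaving the set of
    profiles (and hence any cluster structure among them) intact while
    scrambling which disease carries which profile.
    """
    if scheme == "within_row":
        return rng.permuted(submatrix, axis=1)
    if scheme == "global":
        flat = rng.permutation(submatrix.ravel())
        return flat.reshape(submatrix.shape)
    if scheme == "rows":
        return submatrix[rng.permutation(submatrix.shape[0])]
    raise ValueError(f"unknown permutation scheme {scheme!r}")


@dataclass
class PermutationNull:
    """Chance level of disease-profile correlation.

    ``tail_prob`` is the fraction of permuted off-diagonal correlations
    exceeding ``cutoff``.  ``replicate_ci`` is a 95% interval from the
    per-permutation tail fractions (robust to the dependence between pairs
    that share a row within one permutation); ``binomial_ci`` is the naive
    Wilson interval over all pair indicators.
    """

    tail_prob: float
    cutoff: float
    n_permutations: int
    n_pairs_per_permutation: int
    replicate_ci: tuple[float, float]
    binomial_ci: tuple[float, float]
    scheme: str


def correlation_permutation_null(
    submatrix: pd.DataFrame,
    cutoff: float = 0.25,
    n_permutations: int = 500,
    seed: int = 0,
    scheme: str = "within_row",
) -> PermutationNull:
    """Estimate P(permuted-profile correlation > cutoff)."""
    if not -1.0 <= cutoff < 1.0:
        raise ValueError("cutoff must lie in [-1, 1)")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    X = submatrix.to_numpy(dtype=float)
    m = X.shape[0]
    iu = np.triu_indices(m, k=1)
    fractions = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = permute_profiles(X, rng, scheme)
        corr = np.corrcoef(perm)
        fractions[b] = np.mean(corr[iu] > cutoff)
    tail = float(fractions.mean())
    se = float(fractions.std(ddof=1) / np.sqrt(n_permutations))
    rep_ci = (max(0.0, tail - 1.96 * se), min(1.0, tail + 1.96 * se))
    n_total = n_permutations * len(iu[0])
    k_total = int(round(tail * n_total))
    lo, hi = _wilson(k_total, n_total)
    return PermutationNull(
        tail_prob=tail,
        cutoff=cutoff,
        n_permutations=n_permutations,
        n_pairs_per_permutation=len(iu[0]),
        replicate_ci=rep_ci,
        binomial_ci=(lo, hi),
        scheme=scheme,
    )


def _wilson(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def analytic_null_tail(cutoff: float, n: int) -> float:
    """P(Pearson r > cutoff) for two independent normal n-vectors.

    Uses the exact t transform r*sqrt((n-2)/(1-r^2)) ~ t_{n-2}.
    """
    t = cutoff * np.sqrt((n - 2) / (1.0 - cutoff**2))
    return float(stats.t.sf(t, df=n - 2))


@dataclass
class PartialCorrelationNetwork:
    """Sparse partial correlations between diseases given all others."""

    partial_corr: pd.DataFrame  # m x m, diagonal 0
    edges: pd.DataFrame  # source, target, weight; |weight| > threshold
    alpha: float
    edge_threshold: float


def partial_correlation_network(
    submatrix: pd.DataFrame,
    cv_folds: int = 5,
    edge_threshold: float = 0.1,
    seed: int = 0,
) -> PartialCorrelationNetwork:
    """Graphical-lasso partial-correlation network over disease profiles.

    Diseases are the variables; the biomarker dimensions of the log-HR
    matrix act as observations, standardized per disease.  The penalty is
    chosen by cross-validation over biomarker dimensions; on convergence
    failure the fit is retried along a damped (stronger-penalty) path.
    Edges with ``|partial correlation| <= edge_threshold`` are dropped
    from the edge list while the full matrix is retained.
    """
    m, p = submatrix.shape
    if p <= 2:
        raise ValueError("need more than 2 biomarker columns")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    X = submatrix.to_numpy(dtype=float).T  # p observations x m variables
    X = (X - X.mean(axis=0)) / X.std(axis=0)

    precision, alpha = None, None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gl = GraphicalLassoCV(
                cv=KFold(cv_folds, shuffle=True, random_state=seed)
            ).fit(X)
        precision, alpha = gl.precision_, float(gl.alpha_)
    except (FloatingPointError, ValueError) as err:
        logger.warning("GraphicalLassoCV failed (%s); retrying damped path", err)
        for a in np.geomspace(0.01, 1.0, 8):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = GraphicalLasso(alpha=float(a)).fit(X)
                precision, alpha = fit.precision_, float(a)
                break
            except (FloatingPointError, ValueError):
                continue
        if precision is None:
            raise RuntimeError("graphical lasso failed along the damped path") from err

    d = np.sqrt(np.diag(precision))
    pcor = -precision / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    pcor_df = pd.DataFrame(pcor, index=submatrix.index, columns=submatrix.index)

    iu = np.triu_indices(m, k=1)
    w = pcor[iu]
    keep = np.abs(w) > edge_threshold
    edges = pd.DataFrame(
        {
            "source": submatrix.index[iu[0][keep]],
            "target": submatrix.index[iu[1][keep]],
            "weight": w[keep],
        }
    )
    return PartialCorrelationNetwork(
        partial_corr=pcor_df, edges=edges, alpha=alpha, edge_threshold=edge_threshold
    )
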