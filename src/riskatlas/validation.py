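"""Cluster-enrichment validation against comorbidity structure.

The check asks whether diseases assigned to the same biomarker-profile
cluster co-occur in an independent EHR cohort more often than chance.
At every association threshold tau the True Match Rate is

    TMR(tau) = (pairs with association > tau AND same cluster)
               / (all pairs with association > tau)

integrated over tau with the trapezoidal rule to give an AUC in
tau x TMR units (deliberately not normalized by the tau range).  The
random baseline repeats the whole embed-and-cluster step on permuted
hazard matrices, keeping the chosen hyper-parameters and the same
association matrix, and the Validation Score is the ratio of the actual
AUC to the mean baseline AUC — values above 1 indicate cluster structure
aligned with comorbidity beyond chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import NOISE, density_cluster, embed_2d, grid_search_clustering
from .similarity import permute_profiles

logger = logging.getLogger(__name__)

__all__ = [
    "TMRCurve",
    "BaselineResult",
    "ValidationReport",
    "pair_strengths",
    "tmr_at",
    "tmr_curve",
    "auc_trapezoid",
    "random_baseline",
    "validation_score",
    "validate_clusters",
]


def pair_strengths(assoc: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Unordered-pair association strengths with same-cluster flags.

    The pair universe is every unordered pair of non-noise diseases
    present in both the association matrix and the labels; a pair's
    strength is the larger of its two directed coefficients.
    """
    ids = [d for d in assoc.index if d in labels.index and labels[d] != NOISE]
    rows = []
    for ii in range(len(ids)):
        for jj in range(ii + 1, len(ids)):
            a, b = ids[ii], ids[jj]
            strength = np.nanmax([assoc.loc[a, b], assoc.loc[b, a]])
            rows.append((a, b, float(strength), labels[a] == labels[b]))
    return pd.DataFrame(
        rows, columns=["disease_a", "disease_b", "strength", "same_cluster"]
    )


def tmr_at(
    assoc: pd.DataFrame, labels: pd.Series, tau: float
) -> tuple[float | None, int]:
    """True Match Rate at one association cutoff.

    Returns ``(None, 0)`` when no pair exceeds tau — an undefined point,
    not an error.
    """
    pairs = pair_strengths(assoc, labels)
    above = pairs[pairs["strength"] > tau]
    if len(above) == 0:
        return None, 0
    return float(above["same_cluster"].mean()), int(len(above))


@dataclass
class TMRCurve:
    """TMR as a step function of descending association thresholds."""

    thresholds: np.ndarray  # strictly decreasing
    tmr: np.ndarray  # NaN marks undefined points (no pairs above tau)
    n_pairs: np.ndarray

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.tmr)


def default_tau_grid(assoc: pd.DataFrame, labels: pd.Series) -> np.ndarray:
    """Sorted unique positive pair strengths, descending.

    Evaluating at exactly these values captures the TMR step function
    without interpolation.
    """
    pairs = pair_strengths(assoc, labels)
    vals = pairs.loc[pairs["strength"] > 0, "strength"].unique()
    return np.sort(vals)[::-1]


def tmr_curve(
    assoc: pd.DataFrame,
    labels: pd.Series,
    tau_grid: np.ndarray | None = None,
) -> TMRCurve:
    """Evaluate the TMR at every threshold of the grid."""
    if tau_grid is None:
        tau_grid = default_tau_grid(assoc, labels)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau grid is empty")
    tau_grid = np.sort(np.unique(tau_grid))[::-1]
    pairs = pair_strengths(assoc, labels)
    tmr = np.full(len(tau_grid), np.nan)
    n_pairs = np.zeros(len(tau_grid), dtype=int)
    for i, tau in enumerate(tau_grid):
        above = pairs[pairs["strength"] > tau]
        n_pairs[i] = len(above)
        if len(above):
            tmr[i] = above["same_cluster"].mean()
    return TMRCurve(thresholds=tau_grid, tmr=tmr, n_pairs=n_pairs)


def auc_trapezoid(curve: TMRCurve) -> float:
    """Trapezoidal area under TMR vs tau across the defined points.

    Undefined points (no pairs above tau) are bridged by omission: the
    integral runs over defined points only.  The area carries tau x TMR
    units and is not normalized by the tau range.
    """
    mask = curve.defined()
    if mask.sum() < 2:
        raise ValueError("need at least 2 defined TMR points for an AUC")
    tau = curve.thresholds[mask][::-1]  # ascending for integration
    y = curve.tmr[mask][::-1]
    return float(np.trapezoid(y, x=tau))


@dataclass
class BaselineResult:
    """AUC distribution under permuted-hazard re-clustering."""

    aucs: np.ndarray
    mean: float
    sd: float
    n_replicates: int
    n_resampled: int


def random_baseline(
    submatrix: pd.DataFrame,
    assoc: pd.DataFrame,
    umap_params: dict,
    dbscan_params: dict,
    n_replicates: int = 10,
    seed: int = 0,
    tau_grid: np.ndarray | None = None,
    scheme: str = "rows",
    max_resample: int = 20,
    reoptimize: bool = False,
    umap_grid: dict | None = None,
    dbscan_grid: dict | None = None,
) -> BaselineResult:
    """Random-expectation AUC from permuted hazard matrices.

    Each replicate shuffles the biomarker log-HR matrix, re-runs UMAP and
    DBSCAN, recomputes the TMR curve against the same association matrix,
    and records its AUC.  The default ``rows`` scheme reorders whole
    profiles across diseases: the set of profiles — and therefore the
    number and sizes of the clusters the algorithm finds — is preserved,
    and only the assignment of diseases to profiles is randomized.  This
    keeps the baseline's same-cluster pair fraction comparable to the
    actual run's, so the score isolates cluster/comorbidity alignment
    rather than differences in clustering granularity; entry-level
    schemes (``within_row``, ``global``) are available but tend to yield
    degenerate clusterings (single blob or all noise) whose TMR reflects
    granularity, not alignment.

    By default the already-chosen hyper-parameters are reused (cheap);
    with ``reoptimize=True`` the full grid search is repeated per
    replicate, mirroring the actual procedure more closely.  Replicates
    whose curve has fewer than 2 defined points are resampled up to
    ``max_resample`` times.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    X = submatrix.to_numpy(dtype=float)
    umap_kw = {k: v for k, v in umap_params.items() if k in ("n_neighbors", "min_dist")}
    dbscan_kw = {k: v for k, v in dbscan_params.items() if k in ("eps", "min_samples")}
    aucs = []
    n_resampled = 0
    for _ in range(n_replicates):
        for attempt in range(max_resample):
            perm = pd.DataFrame(
                permute_profiles(X, rng, scheme),
                index=submatrix.index,
                columns=submatrix.columns,
            )
            rep_seed = int(rng.integers(2**31 - 1))
            try:
                if reoptimize:
                    assignment = grid_search_clustering(
                        perm, umap_grid=umap_grid, dbscan_grid=dbscan_grid,
                        seed=rep_seed,
                    )
                    labels = assignment.labels
                else:
                    emb = embed_2d(perm, seed=rep_seed, **umap_kw)
                    labels = density_cluster(emb, **dbscan_kw)
                curve = tmr_curve(assoc, labels, tau_grid)
                aucs.append(auc_trapezoid(curve))
                break
            except ValueError:
                n_resampled += 1
                logger.warning("baseline replicate undefined; resampling")
        else:
            raise RuntimeError(
                "baseline replicate kept producing undefined TMR curves"
            )
    aucs = np.asarray(aucs)
    return BaselineResult(
        aucs=aucs,
        mean=float(aucs.mean()),
        sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        n_replicates=n_replicates,
        n_resampled=n_resampled,
    )


def validation_score(actual_auc: float, baseline_auc: float) -> float:
    """Ratio of actual to random-baseline AUC."""
    if baseline_auc <= 0:
        raise ValueError("baseline AUC must be > 0 for a defined score")
    return float(actual_auc / baseline_auc)


@dataclass
class ValidationReport:
    """Bundle of the actual curve, baseline distribution and score."""

    actual_auc: float
    baseline: BaselineResult
    score: float
    curve: TMRCurve
    seed: int

    def to_dict(self) -> dict:
        return {
            "actual_auc": self.actual_auc,
            "baseline_auc_mean": self.baseline.mean,
            "baseline_auc_sd": self.baseline.sd,
            "validation_score": self.score,
            "n_replicates": self.baseline.n_replicates,
            "seed": self.seed,
        }


def validate_clusters(
    submatrix: pd.DataFrame,
    assoc: pd.DataFrame,
    labels: pd.Series,
    umap_params: dict,
    dbscan_params: dict,
    n_replicates: int = 10,
    seed: int = 0,
    tau_grid: np.ndarray | None = None,
    reoptimize: bool = False,
    umap_grid: dict | None = None,
    dbscan_grid: dict | None = None,
) -> ValidationReport:
    """Full validation: actual AUC, permuted baseline, score."""
    if tau_grid is None:
        tau_grid = default_tau_grid(assoc, labels)
    curve = tmr_curve(assoc, labels, tau_grid)
    actual = auc_trapezoid(curve)
    baseline = random_baseline(
        submatrix,
        assoc,
        umap_params,
        dbscan_params,
        n_replicates=n_replicates,
        seed=seed,
        tau_grid=tau_grid,
        reoptimize=reoptimize,
        umap_grid=umap_grid,
        dbscan_grid=dbscan_grid,
    )
    return ValidationReport(
        actual_auc=actual,
        baseline=baseline,
        score=validation_score(actual, baseline.mean),
        curve=curve,
        seed=seed,
    )
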