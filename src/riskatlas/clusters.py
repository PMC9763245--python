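"""Density-based clustering of the biomarker-hazard disease space.

The biomarker log-HR matrix (diseases x biomarkers) is projected to 2D
with UMAP under the Euclidean metric, clusters are enumerated in the
embedding with DBSCAN, and the hyper-parameters of both steps are chosen
by exhaustive grid search maximizing the silhouette coefficient, with the
Calinski-Harabasz index and Davies-Bouldin score reported alongside.
DBSCAN's noise label (-1) marks diseases with no close profile neighbour;
noise points are excluded from the quality scores so legitimate outlier
detection is not penalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

NOISE = -1

__all__ = ["NOISE", "ClusterAssignment", "embed_2d", "density_cluster",
           "grid_search_clustering", "cluster_profile",
           "DEFAULT_UMAP_GRID", "DEFAULT_DBSCAN_GRID"]

DEFAULT_UMAP_GRID = {
    "n_neighbors": [5, 10, 15, 30],
    "min_dist": [0.0, 0.1, 0.25, 0.5],
}
DEFAULT_DBSCAN_GRID = {
    "eps": [round(e, 1) for e in np.arange(0.1, 1.01, 0.1)],
    "min_samples": [2, 3, 5],
}


@dataclass
class ClusterAssignment:
    """Winning embedding + labels of the grid-searched UMAP->DBSCAN run."""

    embedding: pd.DataFrame  # columns x, y; index diseases
    labels: pd.Series  # integer cluster id, NOISE for outliers
    n_clusters: int
    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float
    chosen_params: dict
    grid_log: pd.DataFrame | None = None


def embed_2d(
    submatrix: pd.DataFrame,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """UMAP projection of disease profiles to 2 dimensions.

    Deterministic for a fixed seed (single-threaded layout).  Requires at
    least ``n_neighbors`` rows.
    """
    import umap  # deferred: numba compilation is slow at import time

    m = submatrix.shape[0]
    if n_neighbors < 2:
        raise ValueError("n_neighbors must be >= 2")
    if m < n_neighbors:
        raise ValueError(
            f"need at least n_neighbors={n_neighbors} diseases, got m={m}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="euclidean",
            random_state=seed,
        )
        coords = reducer.fit_transform(submatrix.to_numpy(dtype=float))
    return pd.DataFrame(coords, columns=["x", "y"], index=submatrix.index)


def density_cluster(
    embedding: pd.DataFrame, eps: float = 0.5, min_samples: int = 3
) -> pd.Series:
    """DBSCAN labels on the 2D embedding; -1 marks noise points."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        embedding[["x", "y"]].to_numpy()
    )
    return pd.Series(labels, index=embedding.index, name="cluster")


def _score_labels(
    points: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, int]:
    """(silhouette, CH, DB, n_clusters) over non-noise points; -inf if <2."""
    mask = labels != NOISE
    kept, kept_labels = points[mask], labels[mask]
    n_clusters = len(set(kept_labels))
    if n_clusters < 2 or len(kept) < n_clusters + 1:
        return -np.inf, -np.inf, np.inf, n_clusters
    return (
        float(silhouette_score(kept, kept_labels)),
        float(calinski_harabasz_score(kept, kept_labels)),
        float(davies_bouldin_score(kept, kept_labels)),
        n_clusters,
    )


def _dedupe(values) -> list:
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def grid_search_clustering(
    submatrix: pd.DataFrame,
    umap_grid: dict | None = None,
    dbscan_grid: dict | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Exhaustive UMAP x DBSCAN grid search maximizing the silhouette.

    Every grid point is scored on the non-noise points of its own 2D
    embedding; points yielding fewer than two clusters score -inf.  Ties
    are broken by higher Calinski-Harabasz, then lower Davies-Bouldin,
    then first-in-grid order.  Each UMAP embedding is computed once and
    shared across the DBSCAN sub-grid.

    The quantity maximized is the silhouette scaled by the fraction of
    non-noise points: scoring only the surviving points would otherwise
    reward solutions that discard most diseases as noise and keep a few
    tight fragments.  Reported quality scores are the raw (unscaled)
    values.
    """
    umap_grid = umap_grid or DEFAULT_UMAP_GRID
    dbscan_grid = dbscan_grid or DEFAULT_DBSCAN_GRID
    nns = _dedupe(umap_grid["n_neighbors"])
    mds = _dedupe(umap_grid["min_dist"])
    epss = _dedupe(dbscan_grid["eps"])
    mss = _dedupe(dbscan_grid["min_samples"])
    if not (nns and mds and epss and mss):
        raise ValueError("grids must be non-empty")

    m = submatrix.shape[0]
    best = None  # (sil, ch, -db, -order) maximized
    best_result = None
    rows = []
    order = 0
    for nn, md in product(nns, mds):
        if nn > m:
            rows.append({"n_neighbors": nn, "min_dist": md, "eps": np.nan,
                         "min_samples": np.nan, "n_clusters": 0,
                         "silhouette": -np.inf, "calinski_harabasz": -np.inf,
                         "davies_bouldin": np.inf, "note": "n_neighbors > m"})
            continue
        emb = embed_2d(submatrix, n_neighbors=nn, min_dist=md, seed=seed)
        pts = emb[["x", "y"]].to_numpy()
        for eps, ms in product(epss, mss):
            labels = density_cluster(emb, eps=eps, min_samples=ms)
            arr = labels.to_numpy()
            sil, ch, db, k = _score_labels(pts, arr)
            kept_frac = float(np.mean(arr != NOISE))
            sel = sil * kept_frac if np.isfinite(sil) else -np.inf
            rows.append({"n_neighbors": nn, "min_dist": md, "eps": eps,
                         "min_samples": ms, "n_clusters": k,
                         "n_noise": int(np.sum(arr == NOISE)),
                         "silhouette": sil, "selection_score": sel,
                         "calinski_harabasz": ch, "davies_bouldin": db,
                         "note": ""})
            key = (sel, ch, -db, -order)
            order += 1
            if np.isfinite(sil) and (best is None or key > best):
                best = key
                best_result = (emb, labels, k, sil, ch, db,
                               {"n_neighbors": nn, "min_dist": md,
                                "eps": eps, "min_samples": ms, "seed": seed})
    if best_result is None:
        raise ValueError(
            "every grid point produced fewer than 2 clusters; widen the grids"
        )
    emb, labels, k, sil, ch, db, params = best_result
    return ClusterAssignment(
        embedding=emb,
        labels=labels,
        n_clusters=k,
        silhouette=sil,
        calinski_harabasz=ch,
        davies_bouldin=db,
        chosen_params=params,
        grid_log=pd.DataFrame(rows),
    )


def cluster_profile(labels: pd.Series, hazards) -> pd.DataFrame:
    """Per-cluster mean hazard-ratio profile.

    ``hazards`` may be a HazardMatrix or a plain diseases x covariates
    frame of hazard ratios.  Means are taken on the log scale and reported
    back as hazard ratios; noise-labeled diseases are excluded.
    """
    hr = getattr(hazards, "hr", hazards)
    common = labels.index.intersection(hr.index)
    if len(common) != len(hr.index):
        raise ValueError("labels are not aligned to hazard matrix rows")
    lab = labels.loc[hr.index]
    keep = lab != NOISE
    if not keep.any():
        raise ValueError("no non-noise clusters to profile")
    log_hr = np.log(hr.loc[keep])
    prof = np.exp(log_hr.groupby(lab[keep]).mean())
    prof.index.name = "cluster"
    return prof
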