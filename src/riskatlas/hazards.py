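"""Per-disease C-index-weighted ensembles of ridge-penalized Cox models.

For each disease we fit one L2-penalized Cox proportional-hazards model per
penalty value on a 70% training split, score every model by Harrell's
concordance index on the held-out 30%, and average the log-hazard
coefficients with weights ``W_i = c_i / sum_j c_j``.  The per-covariate
weighted hazard ratio is ``exp(sum_i W_i * beta_i)``: weights act on the
log scale and the result is exponentiated once, which keeps hazard ratios
positive and makes protective/risk effects symmetric around 1.

The stacked result over all diseases passing an incidence threshold is the
HazardMatrix — the atlas's central object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index as _lifelines_cindex
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import SplineTransformer

logger = logging.getLogger(__name__)

__all__ = [
    "ModelDesign",
    "EnsembleFit",
    "HazardMatrix",
    "drop_correlated_biomarkers",
    "zscale",
    "apply_zscale",
    "concordance_index",
    "fit_cox_ensemble",
    "build_hazard_matrix",
    "write_hazard_matrix",
    "read_hazard_matrix",
]

FIXED_COVARIATES = ["age", "sex", "deprivation", "bmi", "smoking", "sbp"]


def default_penalty_grid(n: int = 20) -> np.ndarray:
    """Evenly spaced ridge penalties spanning 0.01–0.2."""
    return np.linspace(0.01, 0.2, n)


def ensemble_weights(cindex) -> np.ndarray:
    """Normalized C-index weights W_i = c_i / sum_j c_j."""
    c = np.asarray(cindex, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("cindex must be a non-empty 1-D vector")
    if np.any(c <= 0):
        raise ValueError("C-indices must be positive to form weights")
    return c / c.sum()


@dataclass
class ModelDesign:
    """Configuration of the per-disease survival models.

    ``biomarkers`` is the post-pruning panel; ``penalty_grid`` must be
    strictly positive and strictly increasing.  Age enters through a
    degree-4 B-spline basis with interior knots at training-age quintiles.
    """

    biomarkers: list[str]
    fixed_covariates: list[str] = field(default_factory=lambda: list(FIXED_COVARIATES))
    penalty_grid: np.ndarray = field(default_factory=default_penalty_grid)
    split_fraction: float = 0.7
    min_events: int = 10
    spline_degree: int = 4
    spline_knots: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.penalty_grid, dtype=float)
        if grid.ndim != 1 or len(grid) == 0:
            raise ValueError("penalty_grid must be a non-empty 1-D sequence")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("penalty_grid must be strictly positive and increasing")
        self.penalty_grid = grid
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie strictly in (0, 1)")


@dataclass
class EnsembleFit:
    """Result of the penalty-grid ensemble for one disease."""

    disease: str
    per_penalty_betas: pd.DataFrame  # n_penalties x n_covariates, log-HR
    per_penalty_cindex: np.ndarray
    weights: np.ndarray
    weighted_hr: pd.Series  # exp(weighted log-HR) per covariate
    test_cindex_summary: float
    n_cases: int

    @property
    def weighted_log_hr(self) -> pd.Series:
        return np.log(self.weighted_hr)


@dataclass
class HazardMatrix:
    """Diseases x covariates matrix of C-index-weighted hazard ratios."""

    hr: pd.DataFrame
    fixed_columns: list[str]  # non-biomarker columns (incl. age spline basis)
    metadata: pd.DataFrame  # per-disease n_cases, mean_cindex
    excluded: list[str] = field(default_factory=list)

    @property
    def biomarker_columns(self) -> list[str]:
        return [c for c in self.hr.columns if c not in self.fixed_columns]


def drop_correlated_biomarkers(
    panel: pd.DataFrame, threshold: float = 0.7
) -> tuple[list[str], list[str]]:
    """Greedy pruning of highly correlated biomarker columns.

    Walks columns in input order; a column is removed when its absolute
    Pearson correlation with any already-retained column reaches the
    threshold.  Zero-variance columns are removed with a warning since
    correlation is undefined for them.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    retained: list[str] = []
    removed: list[str] = []
    values = panel.to_numpy(dtype=float)
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (np.corrcoef(values, rowvar=False)
                if panel.shape[1] > 1 else np.ones((1, 1)))
    for j, col in enumerate(panel.columns):
        if sd[j] == 0:
            warnings.warn(f"column {col!r} is constant; removed (correlation undefined)")
            removed.append(col)
            continue
        idx = [panel.columns.get_loc(r) for r in retained]
        if idx and np.any(np.abs(corr[j, idx]) >= threshold):
            removed.append(col)
        else:
            retained.append(col)
    return retained, removed


def zscale(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize each column to mean 0, SD 1; return the transform too.

    The returned ``params`` frame (columns ``mean``, ``sd``) is meant to be
    estimated on a training split and re-applied to a test split with
    :func:`apply_zscale`, so no information leaks across the split.
    """
    mean = panel.mean(axis=0)
    sd = panel.std(axis=0, ddof=0)
    bad = sd[sd == 0]
    if len(bad):
        raise ValueError(f"zero-variance column(s): {list(bad.index)}")
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return (panel - mean) / sd, params


def apply_zscale(panel: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    return (panel - params["mean"]) / params["sd"]


def inverse_zscale(panel: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    return panel * params["sd"] + params["mean"]


def concordance_index(
    risk_scores: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Harrell's C: fraction of comparable pairs ranked correctly.

    Higher risk score is expected to pair with shorter event time; tied
    risk scores count 0.5.  Raises ``ValueError`` when censoring leaves no
    comparable pair (distinct from a genuine 0.5).
    """
    risk = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if not (len(risk) == len(t) == len(e)):
        raise ValueError("risk_scores, times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    try:
        # lifelines expects predictions that increase with survival time
        return float(_lifelines_cindex(t, -risk, e))
    except ZeroDivisionError as err:
        raise ValueError("no comparable pairs under this censoring pattern") from err


def _age_spline(ages_train: np.ndarray, degree: int, n_knots: int) -> SplineTransformer:
    st = SplineTransformer(
        degree=degree, n_knots=n_knots, knots="quantile", include_bias=False,
        extrapolation="constant",
    )
    st.fit(np.asarray(ages_train, dtype=float).reshape(-1, 1))
    return st


def _design_frame(
    cohort: pd.DataFrame,
    design: ModelDesign,
    spline: SplineTransformer,
    z_params: pd.DataFrame,
) -> pd.DataFrame:
    parts = []
    if "age" in design.fixed_covariates:
        basis = spline.transform(cohort[["age"]].to_numpy(dtype=float))
        parts.append(
            pd.DataFrame(
                basis,
                columns=[f"age_bs_{i}" for i in range(basis.shape[1])],
                index=cohort.index,
            )
        )
    other = [c for c in design.fixed_covariates if c != "age"]
    if other:
        parts.append(cohort[other].astype(float))
    parts.append(apply_zscale(cohort[design.biomarkers], z_params))
    return pd.concat(parts, axis=1)


def fit_cox_ensemble(
    cohort: pd.DataFrame, disease: str, design: ModelDesign
) -> EnsembleFit:
    """Fit the penalty-grid Cox ensemble for one disease.

    The cohort is split 70/30 stratified by event status, biomarkers are
    z-scaled with training-split parameters, and each ridge penalty yields
    one fit whose held-out C-index becomes its ensemble weight.
    Penalties whose fit fails to converge are dropped with a warning; the
    disease errors out only if every penalty fails.
    """
    tcol, ecol = f"{disease}_time", f"{disease}_event"
    if tcol not in cohort or ecol not in cohort:
        raise KeyError(f"cohort has no outcome columns for disease {disease!r}")
    events = cohort[ecol].to_numpy()
    train, test = train_test_split(
        cohort,
        train_size=design.split_fraction,
        stratify=events,
        random_state=design.seed,
    )
    if train[ecol].sum() < design.min_events or test[ecol].sum() < design.min_events:
        raise ValueError(
            f"disease {disease!r} has fewer than {design.min_events} events "
            "in one of the splits"
        )
    _, z_params = zscale(train[design.biomarkers])
    spline = _age_spline(
        train["age"].to_numpy(), design.spline_degree, design.spline_knots
    )
    X_train = _design_frame(train, design, spline, z_params)
    X_test = _design_frame(test, design, spline, z_params)

    fit_df = X_train.copy()
    fit_df["T"] = train[tcol].to_numpy()
    fit_df["E"] = train[ecol].to_numpy()

    betas, cidx, kept = [], [], []
    for pen in design.penalty_grid:
        cph = CoxPHFitter(penalizer=float(pen), l1_ratio=0.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(fit_df, duration_col="T", event_col="E")
        except (ConvergenceError, ValueError) as err:
            logger.warning("penalty %.4g dropped for %s: %s", pen, disease, err)
            continue
        beta = cph.params_.reindex(X_train.columns)
        risk = X_test.to_numpy() @ beta.to_numpy()
        c = concordance_index(risk, test[tcol].to_numpy(), test[ecol].to_numpy())
        betas.append(beta)
        cidx.append(c)
        kept.append(float(pen))
    if not betas:
        raise RuntimeError(f"all penalties failed to converge for disease {disease!r}")

    beta_mat = pd.DataFrame(betas, index=pd.Index(kept, name="penalty"))
    c = np.asarray(cidx)
    weights = ensemble_weights(c)
    weighted_beta = pd.Series(weights @ beta_mat.to_numpy(), index=beta_mat.columns)
    return EnsembleFit(
        disease=disease,
        per_penalty_betas=beta_mat,
        per_penalty_cindex=c,
        weights=weights,
        weighted_hr=np.exp(weighted_beta),
        test_cindex_summary=float(c.mean()),
        n_cases=int(events.sum()),
    )


def build_hazard_matrix(
    cohort: pd.DataFrame,
    design: ModelDesign,
    incidence_threshold: int = 50,
    diseases: list[str] | None = None,
) -> HazardMatrix:
    """Fit the ensemble for every qualifying disease and stack the HRs.

    A disease qualifies when its total case count reaches
    ``incidence_threshold``; skipped diseases are listed in ``excluded``.
    """
    if diseases is None:
        diseases = [c[: -len("_event")] for c in cohort.columns if c.endswith("_event")]
    rows, meta, excluded = [], [], []
    for d in diseases:
        n_cases = int(cohort[f"{d}_event"].sum())
        if n_cases < incidence_threshold:
            excluded.append(d)
            continue
        fit = fit_cox_ensemble(cohort, d, design)
        rows.append(fit.weighted_hr.rename(d))
        meta.append({"disease": d, "n_cases": n_cases,
                     "mean_cindex": fit.test_cindex_summary})
    if not rows:
        raise ValueError(
            f"no disease reaches incidence_threshold={incidence_threshold}"
        )
    hr = pd.DataFrame(rows)
    hr.index.name = "disease"
    fixed = [c for c in hr.columns if c not in design.biomarkers]
    return HazardMatrix(
        hr=hr,
        fixed_columns=fixed,
        metadata=pd.DataFrame(meta).set_index("disease"),
        excluded=excluded,
    )


def write_hazard_matrix(hm: HazardMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hm.hr.to_csv(out / "hazards.tsv", sep="\t")
    hm.metadata.to_csv(out / "hazard_metrics.tsv", sep="\t")
    (out / "hazard_columns.tsv").write_text(
        "\n".join(["column\trole"]
                  + [f"{c}\tfixed" for c in hm.fixed_columns]
                  + [f"{c}\tbiomarker" for c in hm.biomarker_columns]) + "\n"
    )


def read_hazard_matrix(out_dir: str | Path) -> HazardMatrix:
    out = Path(out_dir)
    hr = pd.read_csv(out / "hazards.tsv", sep="\t", index_col="disease")
    meta = pd.read_csv(out / "hazard_metrics.tsv", sep="\t", index_col="disease")
    roles = pd.read_csv(out / "hazard_columns.tsv", sep="\t")
    fixed = roles.loc[roles["role"] == "fixed", "column"].tolist()
    return HazardMatrix(hr=hr, fixed_columns=fixed, metadata=meta)
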