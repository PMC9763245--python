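"""Synthetic cohort and EHR generators.

Every downstream stage of the atlas (hazard profiling, similarity maps,
clustering, comorbidity models, cluster validation) is exercised on data
produced here.  The generator plants a known ground truth — per-disease
log-hazard coefficient vectors drawn around a small number of latent
"archetype" risk profiles — so recovery can be measured exactly.

Two independent tables are produced:

* a prospective cohort with baseline covariates, a correlated continuous
  biomarker panel, and right-censored time-to-first-diagnosis outcomes
  simulated from a Cox model with constant baseline hazard;
* a retrospective EHR-style binary co-occurrence table whose pairwise odds
  structure follows the same archetype clusters, mimicking an independent
  hospitalization cohort.

All functions are pure in their arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ArchetypeSpec",
    "SyntheticCohort",
    "generate_biomarkers",
    "generate_disease_effects",
    "simulate_survival",
    "simulate_ehr",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "write_ehr",
    "read_ehr",
]

#: covariate columns every cohort table carries, in order
COVARIATE_COLUMNS = ["age", "sex", "deprivation", "bmi", "smoking", "sbp"]

# Linear-predictor ceiling: exp() of anything larger is astronomically far
# from plausible per-year hazards and signals a mis-scaled effect size.
_LP_MAX = 30.0


@dataclass(frozen=True)
class ArchetypeSpec:
    """Ground-truth layout of latent risk-profile groups.

    Parameters
    ----------
    n_archetypes:
        Number of latent risk profiles (the true cluster count).
    n_diseases:
        Number of diseases; each disease belongs to exactly one archetype.
    n_biomarkers:
        Length of every coefficient vector.
    effect_scale:
        SD of archetype log-hazard entries, per SD of biomarker.
    within_archetype_noise:
        SD of the per-disease perturbation around its archetype.
    sparsity:
        Fraction of each archetype's entries forced to exactly zero.
    """

    n_archetypes: int = 4
    n_diseases: int = 40
    n_biomarkers: int = 20
    effect_scale: float = 0.15
    within_archetype_noise: float = 0.03
    sparsity: float = 0.3

    def __post_init__(self) -> None:
        if self.n_archetypes < 1:
            raise ValueError("n_archetypes must be >= 1")
        if self.n_diseases < self.n_archetypes:
            raise ValueError(
                f"n_diseases ({self.n_diseases}) must be >= n_archetypes "
                f"({self.n_archetypes})"
            )
        if self.n_biomarkers < 1:
            raise ValueError("n_biomarkers must be >= 1")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be > 0")
        if self.within_archetype_noise < 0:
            raise ValueError("within_archetype_noise must be >= 0")


def generate_biomarkers(
    n_subjects: int,
    n_biomarkers: int,
    block_correlation: float = 0.3,
    n_blocks: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a correlated biomarker panel.

    Multivariate normal with block-diagonal correlation: columns are
    equicorrelated at ``block_correlation`` within a block and independent
    across blocks; every column has population mean 0 and variance 1.
    Blocks partition the columns as evenly as possible.
    """
    if not 0.0 <= block_correlation < 1.0:
        raise ValueError(
            f"block_correlation={block_correlation} with n_blocks={n_blocks} "
            "does not define a valid positive-definite correlation; "
            "require 0 <= block_correlation < 1"
        )
    if n_blocks > n_biomarkers:
        raise ValueError(
            f"n_blocks ({n_blocks}) cannot exceed n_biomarkers ({n_biomarkers})"
        )
    rng = np.random.default_rng(seed)
    rho = block_correlation
    cols = []
    sizes = [len(b) for b in np.array_split(np.arange(n_biomarkers), n_blocks)]
    for size in sizes:
        shared = rng.standard_normal((n_subjects, 1))
        eps = rng.standard_normal((n_subjects, size))
        # x = sqrt(rho)*shared + sqrt(1-rho)*eps gives exact equicorrelation rho
        cols.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps)
    panel = np.concatenate(cols, axis=1)
    names = [f"bm_{i:02d}" for i in range(n_biomarkers)]
    return pd.DataFrame(panel, columns=names)


def generate_disease_effects(
    spec: ArchetypeSpec, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the true log-hazard coefficient matrix and cluster labels.

    Archetype vectors are drawn once from N(0, effect_scale²) with
    ``round(sparsity * p)`` entries zeroed per archetype; each disease's
    vector is its archetype plus independent N(0, within_archetype_noise²)
    noise.  Diseases are assigned to archetypes in balanced contiguous
    groups, so the returned labels are the ground-truth clusters.
    """
    rng = np.random.default_rng(seed)
    k, m, p = spec.n_archetypes, spec.n_diseases, spec.n_biomarkers
    archetypes = rng.normal(0.0, spec.effect_scale, size=(k, p))
    n_zero = int(round(spec.sparsity * p))
    for a in range(k):
        zero_idx = rng.choice(p, size=n_zero, replace=False)
        archetypes[a, zero_idx] = 0.0
    labels = np.concatenate(
        [np.full(len(g), i) for i, g in enumerate(np.array_split(np.arange(m), k))]
    )
    betas = archetypes[labels] + rng.normal(
        0.0, spec.within_archetype_noise, size=(m, p)
    )
    disease_ids = pd.Index([f"D{i:03d}" for i in range(m)], name="disease")
    marker_ids = [f"bm_{i:02d}" for i in range(p)]
    return pd.DataFrame(betas, index=disease_ids, columns=marker_ids), labels


def simulate_survival(
    biomarkers: pd.DataFrame,
    true_betas: pd.DataFrame,
    baseline_rate: float = 0.005,
    horizon: float = 12.0,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    covariate_effects: dict[str, float] | None = None,
    age_polynomial: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Simulate right-censored time-to-first-diagnosis outcomes per disease.

    Onset times are exponential with subject rate ``h0 * exp(x'beta)``
    (constant baseline hazard), administratively censored at ``horizon``
    years: ``event = 1`` iff onset occurred by the horizon, and censored
    subjects carry ``time = horizon``.

    ``covariate_effects`` maps covariate names to log-hazard coefficients
    applied to mean-centred covariate values; ``age_polynomial`` gives
    coefficients (c1, c2, ...) of a polynomial in centred age added to the
    linear predictor, letting a nonlinear age effect exist for the
    downstream spline adjustment to absorb.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    rng = np.random.default_rng(seed)
    X = biomarkers[true_betas.columns].to_numpy()
    lp = X @ true_betas.to_numpy().T  # n_subjects x n_diseases

    if covariates is not None and covariate_effects:
        for name, coef in covariate_effects.items():
            v = covariates[name].to_numpy(dtype=float)
            lp += coef * (v - v.mean())[:, None]
    if covariates is not None and age_polynomial:
        a = covariates["age"].to_numpy(dtype=float)
        a = a - a.mean()
        poly = sum(c * a ** (d + 1) for d, c in enumerate(age_polynomial))
        lp += poly[:, None]

    if np.abs(lp).max() > _LP_MAX:
        raise OverflowError(
            "linear predictor exceeds a safe range for exp(); "
            "reduce effect_scale or covariate effect sizes"
        )
    rate = baseline_rate * np.exp(lp)
    onset = rng.exponential(1.0 / rate)
    event = onset <= horizon
    time = np.where(event, onset, horizon)

    out = {}
    for j, disease in enumerate(true_betas.index):
        out[f"{disease}_time"] = time[:, j]
        out[f"{disease}_event"] = event[:, j].astype(int)
    return pd.DataFrame(out)


def _solve_mixture(p: float, target_or: float) -> tuple[float, float, float]:
    """Find (q, p1, p0) of a two-point susceptibility mixture.

    A fraction ``q`` of subjects is susceptible to a cluster; diseases in
    the cluster occur with probability ``p1`` (susceptible) or ``p0``, with
    marginal prevalence ``p`` and marginal pairwise odds ratio
    ``target_or`` between any two diseases of the cluster.  ``q`` is taken
    from a fixed descending ladder, smallest mixture distortion first.
    """

    def pair_or(q: float, delta: float) -> float:
        p1 = p + (1.0 - q) * delta
        p0 = p - q * delta
        p11 = q * p1**2 + (1.0 - q) * p0**2
        p10 = p - p11
        p00 = 1.0 - 2.0 * p + p11
        return (p11 * p00) / (p10 * p10)

    for q in (0.5, 0.3, 0.2, 0.1, 0.05, 0.02):
        delta_max = min(p / q, (1.0 - p) / (1.0 - q))
        hi = delta_max * (1.0 - 1e-9)
        if pair_or(q, hi) < target_or:
            continue
        delta = brentq(lambda d: pair_or(q, d) - target_or, 0.0, hi)
        return q, p + (1.0 - q) * delta, p - q * delta
    raise ValueError(
        f"within_cluster_or={target_or} is unattainable at "
        f"base_prevalence={p}: implied conditional probabilities leave (0, 1)"
    )


def simulate_ehr(
    true_cluster_labels: np.ndarray,
    n_subjects: int = 50_000,
    base_prevalence: float = 0.1,
    within_cluster_or: float = 4.0,
    seed: int = 0,
    disease_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Generate an independent binary disease co-occurrence table.

    Each subject draws one latent binary susceptibility per cluster;
    diseases of a cluster are conditionally independent Bernoulli given
    that susceptibility, calibrated so every disease has marginal
    prevalence ``base_prevalence`` and every same-cluster pair has
    marginal odds ratio ``within_cluster_or``.  Cross-cluster pairs are
    independent.
    """
    if not 0.0 < base_prevalence < 1.0:
        raise ValueError("base_prevalence must lie strictly in (0, 1)")
    if within_cluster_or < 1.0:
        raise ValueError("within_cluster_or must be >= 1")
    labels = np.asarray(true_cluster_labels)
    m = len(labels)
    if disease_ids is None:
        disease_ids = [f"D{i:03d}" for i in range(m)]
    rng = np.random.default_rng(seed)

    if within_cluster_or == 1.0:
        mat = (rng.random((n_subjects, m)) < base_prevalence).astype(np.int8)
        return pd.DataFrame(mat, columns=disease_ids)

    q, p1, p0 = _solve_mixture(base_prevalence, within_cluster_or)
    clusters = np.unique(labels)
    susceptible = rng.random((n_subjects, len(clusters))) < q
    mat = np.empty((n_subjects, m), dtype=np.int8)
    for j in range(m):
        c = np.searchsorted(clusters, labels[j])
        prob = np.where(susceptible[:, c], p1, p0)
        mat[:, j] = rng.random(n_subjects) < prob
    return pd.DataFrame(mat, columns=disease_ids)


# default covariate log-hazard coefficients for the simulated cohort
DEFAULT_COVARIATE_EFFECTS = {
    "sex": 0.2,
    "deprivation": 0.02,
    "bmi": 0.02,
    "smoking": 0.3,
    "sbp": 0.004,
}
#: mild nonlinear age trend (per centred year, quadratic term)
DEFAULT_AGE_POLYNOMIAL = (0.04, 0.0008)


@dataclass
class SyntheticCohort:
    """Cohort table bundled with its planted ground truth."""

    table: pd.DataFrame
    true_betas: pd.DataFrame
    true_labels: np.ndarray
    spec: ArchetypeSpec
    params: dict = field(default_factory=dict)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.true_betas.index)

    @property
    def biomarker_ids(self) -> list[str]:
        return list(self.true_betas.columns)


def generate_cohort(
    n_subjects: int = 20_000,
    spec: ArchetypeSpec | None = None,
    block_correlation: float = 0.3,
    n_blocks: int = 4,
    baseline_rate: float = 0.005,
    horizon: float = 12.0,
    covariate_effects: dict[str, float] | None = None,
    age_polynomial: tuple[float, ...] | None = None,
    sex_linked_markers: tuple[int, int] | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Assemble a full synthetic cohort: covariates, biomarkers, outcomes.

    Covariate marginals loosely follow a middle-aged population cohort
    (age uniform 40–70, Townsend-style deprivation index, BMI ~ N(27, 4.5²),
    systolic BP ~ N(138, 18²)).  ``sex_linked_markers`` optionally shifts two
    designated biomarker columns by +1.5 SD in one sex to exercise the
    downstream sex-marker exclusion rule.

    Defaults are the package's reference study conditions; pass explicit
    values to scale experiments up or down.
    """
    if spec is None:
        spec = ArchetypeSpec()
    if covariate_effects is None:
        covariate_effects = dict(DEFAULT_COVARIATE_EFFECTS)
    if age_polynomial is None:
        age_polynomial = DEFAULT_AGE_POLYNOMIAL
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=3)

    cov = pd.DataFrame(
        {
            "age": rng.uniform(40.0, 70.0, n_subjects),
            "sex": rng.integers(0, 2, n_subjects).astype(float),
            "deprivation": rng.normal(-1.3, 3.0, n_subjects),
            "bmi": rng.normal(27.0, 4.5, n_subjects),
            "smoking": (rng.random(n_subjects) < 0.1).astype(float),
            "sbp": rng.normal(138.0, 18.0, n_subjects),
        }
    )
    bm = generate_biomarkers(
        n_subjects, spec.n_biomarkers, block_correlation, n_blocks, seed=int(sub_seeds[0])
    )
    if sex_linked_markers is not None:
        for idx in sex_linked_markers:
            bm.iloc[:, idx] = bm.iloc[:, idx] + 1.5 * cov["sex"].to_numpy()
    betas, labels = generate_disease_effects(spec, seed=int(sub_seeds[1]))
    outcomes = simulate_survival(
        bm,
        betas,
        baseline_rate=baseline_rate,
        horizon=horizon,
        seed=int(sub_seeds[2]),
        covariates=cov,
        covariate_effects=covariate_effects,
        age_polynomial=age_polynomial,
    )
    table = pd.concat([cov, bm, outcomes], axis=1)
    table.insert(0, "subject_id", [f"S{i:06d}" for i in range(n_subjects)])
    params = {
        "n_subjects": n_subjects,
        "block_correlation": block_correlation,
        "n_blocks": n_blocks,
        "baseline_rate": baseline_rate,
        "horizon": horizon,
        "covariate_effects": covariate_effects,
        "age_polynomial": list(age_polynomial),
        "sex_linked_markers": list(sex_linked_markers) if sex_linked_markers else None,
        "seed": seed,
        "spec": asdict(spec),
    }
    return SyntheticCohort(table, betas, labels, spec, params)


# ---------------------------------------------------------------------------
# plain-text persistence (wide CSV + truth sidecar + JSON parameter header)

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(out / "cohort.csv", index=False)
    truth = cohort.true_betas.copy()
    truth.insert(0, "cluster", cohort.true_labels)
    truth.to_csv(out / "truth.csv", index_label="disease")
    (out / "cohort.json").write_text(json.dumps(cohort.params, indent=2))


def read_cohort(out_dir: str | Path) -> SyntheticCohort:
    out = Path(out_dir)
    table = pd.read_csv(out / "cohort.csv")
    truth = pd.read_csv(out / "truth.csv", index_col="disease")
    params = json.loads((out / "cohort.json").read_text())
    labels = truth.pop("cluster").to_numpy()
    spec = ArchetypeSpec(**params["spec"])
    return SyntheticCohort(table, truth, labels, spec, params)


def write_ehr(ehr: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    ehr.to_csv(path, index=False)
    if params is not None:
        path.with_suffix(".json").write_text(json.dumps(params, indent=2))


def read_ehr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
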