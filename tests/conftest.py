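import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import riskatlas as ra

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

logging.getLogger("riskatlas").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort() -> ra.SyntheticCohort:
    """3 archetypes x 9 diseases, 10 biomarkers, 4000 subjects."""
    spec = ra.ArchetypeSpec(
        n_archetypes=3,
        n_diseases=9,
        n_biomarkers=10,
        effect_scale=0.25,
        within_archetype_noise=0.02,
    )
    return ra.generate_cohort(n_subjects=4000, spec=spec, seed=11)


@pytest.fixture(scope="session")
def small_design(small_cohort) -> ra.ModelDesign:
    return ra.ModelDesign(
        biomarkers=small_cohort.biomarker_ids,
        penalty_grid=np.linspace(0.01, 0.2, 3),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_hazards(small_cohort, small_design) -> ra.HazardMatrix:
    return ra.build_hazard_matrix(
        small_cohort.table, small_design, incidence_threshold=50
    )


@pytest.fixture(scope="session")
def archetype_profiles():
    """True log-HR matrix with 4 well-separated archetypes, 24 diseases."""
    spec = ra.ArchetypeSpec(
        n_archetypes=4,
        n_diseases=24,
        n_biomarkers=20,
        effect_scale=0.3,
        within_archetype_noise=0.02,
    )
    betas, labels = ra.generate_disease_effects(spec, seed=3)
    return betas, labels


@pytest.fixture(scope="session")
def clustered_ehr(archetype_profiles):
    betas, labels = archetype_profiles
    ehr = ra.simulate_ehr(
        labels,
        n_subjects=4000,
        base_prevalence=0.1,
        within_cluster_or=4.0,
        seed=3,
        disease_ids=list(betas.index),
    )
    return ehr


@pytest.fixture(scope="session")
def clustered_assoc(clustered_ehr):
    return ra.association_matrix(clustered_ehr, seed=3, min_cases=50)


@pytest.fixture()
def hand_assoc():
    """4 diseases, 2 clusters, hand-set symmetric association table.

    Pair strengths: AB=0.5 (same cluster), CD=0.45 (same), AC=0.4 (cross),
    AD=0.3 (cross), BC=0.05 (cross), BD=0 (same... B and D are in
    different clusters; value 0 keeps it out of every positive cutoff).
    """
    ids = list("ABCD")
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b, v in [("A", "B", 0.5), ("C", "D", 0.45), ("A", "C", 0.4),
                    ("A", "D", 0.3), ("B", "C", 0.05)]:
        mat.loc[a, b] = mat.loc[b, a] = v
    np.fill_diagonal(mat.values, np.nan)
    labels = pd.Series([0, 0, 1, 1], index=ids)
    return mat, labels
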