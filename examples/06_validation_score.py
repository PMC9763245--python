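"""End-to-end cluster validation against comorbidity structure.

Clusters the disease space, computes the True Match Rate curve of the
clusters against lasso-logistic comorbidity associations, integrates it
into a trapezoidal AUC, and compares against the AUC distribution under
profile-permuted re-clusterings.  A Validation Score above 1 means the
biomarker clusters predict co-occurrence beyond chance.
"""

import numpy as np

import riskatlas as ra

UMAP_GRID = {"n_neighbors": [5, 10], "min_dist": [0.0, 0.1]}
DBSCAN_GRID = {"eps": [0.3, 0.5, 0.8], "min_samples": [2, 3]}

spec = ra.ArchetypeSpec(n_archetypes=4, n_diseases=24, n_biomarkers=20,
                        effect_scale=0.3, within_archetype_noise=0.02)
betas, labels = ra.generate_disease_effects(spec, seed=2)

assignment = ra.grid_search_clustering(betas, UMAP_GRID, DBSCAN_GRID, seed=2)
print(f"clusters: {assignment.n_clusters} "
      f"(silhouette {assignment.silhouette:.3f})")

ehr = ra.simulate_ehr(labels, n_subjects=3000, base_prevalence=0.1,
                      within_cluster_or=4.0, seed=2,
                      disease_ids=list(betas.index))
assoc = ra.association_matrix(ehr, seed=2, min_cases=50)

report = ra.validate_clusters(betas, assoc, assignment.labels,
                              assignment.chosen_params,
                              assignment.chosen_params,
                              n_replicates=8, seed=2)

defined = report.curve.defined()
print(f"TMR curve: {defined.sum()} defined thresholds, "
      f"TMR at loosest tau {report.curve.tmr[defined][-1]:.3f}")
print(f"actual AUC:   {report.actual_auc:.3f}")
print(f"baseline AUC: {report.baseline.mean:.3f} +/- {report.baseline.sd:.3f} "
      f"({report.baseline.n_replicates} permuted replicates)")
print(f"validation score: {report.score:.2f}")
print("  -> same-cluster pairs dominate the high-association region; the "
      "score is the fold enrichment over profile-permuted clusterings")
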