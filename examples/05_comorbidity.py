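"""Comorbidity associations from an EHR-style co-occurrence table.

Fits one lasso-logistic model per disease on the indicators of all
others, compares two independent cohorts drawn from the same cluster
truth, and asks how often biomarker-similar disease pairs are comorbid.
"""

import numpy as np

import riskatlas as ra

spec = ra.ArchetypeSpec(n_archetypes=4, n_diseases=24, n_biomarkers=20,
                        effect_scale=0.3, within_archetype_noise=0.02)
betas, labels = ra.generate_disease_effects(spec, seed=9)
ids = list(betas.index)

ehr_a = ra.simulate_ehr(labels, n_subjects=4000, base_prevalence=0.1,
                        within_cluster_or=4.0, seed=9, disease_ids=ids)
ehr_b = ra.simulate_ehr(labels, n_subjects=4000, base_prevalence=0.1,
                        within_cluster_or=4.0, seed=10, disease_ids=ids)

assoc_a = ra.association_matrix(ehr_a, seed=9, min_cases=50)
assoc_b = ra.association_matrix(ehr_b, seed=9, min_cases=50)

vals = assoc_a.to_numpy()
same = np.equal.outer(labels, labels) & ~np.eye(len(ids), dtype=bool)
print(f"mean log-odds coefficient, same cluster:  "
      f"{np.nanmean(vals[same]):+.3f}")
print(f"mean log-odds coefficient, cross cluster: "
      f"{np.nanmean(vals[~same & ~np.eye(len(ids), dtype=bool)]):+.3f}")

rep = ra.cross_cohort_concordance(assoc_a, assoc_b)
print(f"\ncross-cohort agreement: Pearson r = {rep.r:.3f}, "
      f"R^2 = {rep.r2:.3f} over {rep.n_pairs} directed pairs")
print("  -> two independent cohorts with the same disease-cluster truth "
      "give concordant association structure")

sim = ra.comorbid_given_similar(ra.disease_correlation(betas), assoc_a,
                                corr_threshold=0.5, assoc_threshold=0.1)
print(f"\nP(comorbid | biomarker correlation >= 0.5) = {sim.fraction:.2f} "
      f"({len(sim.concordant)} concordant, {len(sim.discordant)} discordant "
      "pairs)")
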