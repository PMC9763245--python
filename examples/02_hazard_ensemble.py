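"""Fit the C-index-weighted ridge-Cox ensemble for one disease.

Each penalty in the grid yields one Cox fit on a 70% training split; the
held-out C-index of every fit becomes its ensemble weight, and the
per-covariate weighted hazard ratio is exp of the weighted mean log-HR.
"""

import numpy as np
from scipy.stats import spearmanr

import riskatlas as ra

spec = ra.ArchetypeSpec(n_archetypes=2, n_diseases=4, n_biomarkers=10,
                        effect_scale=0.25, within_archetype_noise=0.02)
cohort = ra.generate_cohort(n_subjects=8000, spec=spec, seed=7)

design = ra.ModelDesign(biomarkers=cohort.biomarker_ids,
                        penalty_grid=np.linspace(0.01, 0.2, 5), seed=7)
fit = ra.fit_cox_ensemble(cohort.table, "D000", design)

print(f"disease D000: {fit.n_cases} cases")
print(f"per-penalty test C-index: {np.round(fit.per_penalty_cindex, 3)}")
print(f"ensemble weights (sum {fit.weights.sum():.6f}): "
      f"{np.round(fit.weights, 3)}")
print("\nweighted hazard ratios per biomarker vs planted truth:")
truth = cohort.true_betas.loc["D000"]
for marker in cohort.biomarker_ids:
    print(f"  {marker}: HR {fit.weighted_hr[marker]:.3f} "
          f"(true beta {truth[marker]:+.3f})")
rho = spearmanr(fit.weighted_log_hr[cohort.biomarker_ids], truth).statistic
print(f"\nSpearman(weighted log-HR, true beta) = {rho:.3f}")
print("  -> HR > 1 marks risk markers, HR < 1 protective ones; the rank "
      "agreement shows the ensemble recovers the planted profile")
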