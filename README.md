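# riskatlas

A reusable pipeline for building a **prognostic-biomarker disease atlas**:
given a cohort with baseline clinical biomarkers and long-term
time-to-first-diagnosis outcomes, it profiles every disease by a vector of
hazard ratios, maps the similarity structure of the disease space, clusters
diseases by risk profile, and checks whether those clusters predict disease
co-occurrence in an independent EHR cohort.

It is written for biostatisticians and epidemiologists who want the whole
chain — survival modeling, similarity mapping, density clustering,
comorbidity modeling and cluster validation — as tested, composable library
functions rather than a one-off analysis script.  Because real biobank and
hospitalization data are access-controlled, the package ships a seeded
synthetic-cohort generator with planted ground truth (latent risk-profile
"archetypes"), so every stage can be exercised and validated end to end.

## The methods

**Hazard profiling.** For each disease the instantaneous risk follows a Cox
proportional-hazards model

    h_i(t) = h_0(t) · exp( Σ_j β_j x_ij )

with z-scaled biomarkers and a fixed covariate block (degree-4 B-spline in
age, sex, deprivation index, BMI, smoking, systolic blood pressure).
Instead of one model per disease, an ensemble of L2-penalized fits over a
ridge-penalty grid (0.01–0.2) is trained on a 70% split; each fit is scored
by Harrell's concordance index `c_i` on the held-out 30% and the
coefficients are combined with weights

    W_i = c_i / Σ_j c_j

The per-covariate weighted hazard ratio `exp(Σ_i W_i β_i)` forms one row of
the **hazard matrix** (diseases × covariates), the atlas's central object.

**Similarity and clustering.** Disease similarity is the Pearson
correlation of the biomarker-only log-HR profiles (fixed covariates and
strongly sex-linked markers excluded), with a permutation null for the
chance level and a cross-validated graphical-lasso partial-correlation
network.  The profile matrix is projected to 2D with UMAP and clustered
with DBSCAN; both stages' hyper-parameters are chosen by exhaustive grid
search on the silhouette coefficient (Calinski-Harabasz and Davies-Bouldin
reported alongside).

**Comorbidity and validation.** From a binary co-occurrence table, each
disease is regressed on all others with 5-fold cross-validated lasso
logistic regression; the log-odds coefficients form a directed association
matrix (≥ 0.1, i.e. OR > 1.1, counts as comorbid).  The clusters are
validated by the **True Match Rate**

    TMR(τ) = (# pairs with association > τ in the same cluster)
             / (# pairs with association > τ)

integrated over τ by the trapezoidal rule, and the **Validation Score** is
the ratio of this AUC to its mean under re-clusterings of profile-permuted
hazard matrices.  Scores above 1 mean biomarker-profile clusters predict
co-occurrence beyond chance.

## Worked example

`examples/06_validation_score.py` runs the validation chain on a synthetic
disease space with 4 archetypes, 24 diseases and a co-occurrence cohort
whose same-cluster odds ratio is 4:

```
clusters: 4 (silhouette 0.974)
TMR curve: 78 defined thresholds, TMR at loosest tau 0.769
actual AUC:   0.979
baseline AUC: 0.217 +/- 0.043 (8 permuted replicates)
validation score: 4.51
```

The grid-searched UMAP→DBSCAN run recovers the 4 planted archetypes; the
TMR-curve area for the real labels (0.979) is ~4.5× the mean area under
profile-permuted re-clusterings (0.217), i.e. same-cluster disease pairs
are strongly enriched among high-association pairs.  The other scripts in
`examples/` demonstrate each capability separately (cohort simulation,
the Cox ensemble, the similarity map, the cluster atlas, comorbidity
models), each printing the quantities it computes and what they mean.

A thin CLI mirrors the pipeline for shell use:

```bash
atlas simulate --config config.yaml --seed 1 --out data/
atlas fit --cohort data/cohort.csv --out hazards/
atlas similarity --hazards hazards/ --out sim/
atlas cluster --hazards hazards/ --out clusters/
atlas comorbidity --ehr data/ehr.csv --out assoc.tsv
atlas validate --hazards hazards/ --assoc assoc.tsv \
    --clusters clusters/clusters.tsv --params '{"n_neighbors": 10,
    "min_dist": 0.1, "eps": 0.5, "min_samples": 2}' --out validation/
```

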