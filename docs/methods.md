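# Methods

This note documents the models implemented in `riskatlas`, the defaults
and why they were chosen, the numerical decisions that were genuinely
open, and what results on the synthetic generator do and do not show.

## Synthetic cohort generator

The generator exists because the data this kind of atlas is built from
(biobank baselines with longitudinal diagnoses; hospitalization records)
are access-controlled.  It emulates the statistical structure the
analysis assumes, with planted ground truth for every recovery check.

**Biomarkers.** Multivariate normal with block-diagonal correlation:
equicorrelated within a block (default ρ = 0.3, 4 blocks), independent
across blocks, population mean 0 / variance 1 per column.  The block
structure exists so the downstream correlation-pruning rule (drop a
column at |r| ≥ 0.7 against a retained one) has something to act on when
configured with higher ρ.  Two designated columns can be made strongly
sex-dependent (+1.5 SD in one sex) to exercise the sex-marker exclusion.

**Disease effects.** A small number of archetype log-hazard vectors are
drawn from N(0, effect_scale²) with a fraction of entries forced to zero
(`sparsity`, default 0.3); each disease's true coefficient vector is its
archetype plus N(0, within_archetype_noise²) noise.  Diseases are
assigned to archetypes in balanced groups — the ground-truth cluster
labels.  Defaults (effect_scale 0.15 per biomarker SD, i.e. hazard
ratios mostly in 0.74–1.35) are in the range typically reported for
standardized clinical biomarkers; "well-separated" test configurations
use effect_scale 0.3 with noise 0.02.

**Outcomes.** Onset times are exponential with subject rate
h₀·exp(xᵀβ): the baseline hazard is constant.  Since the partial
likelihood estimates only β and factors h₀(t) out, the simplest baseline
suffices and gives closed-form oracles (event probability
1 − exp(−h₀·T) under the null).  Administrative censoring at the horizon
(default 12 years, a typical biobank follow-up); h₀ defaults to
0.005/person-year, giving ~6% twelve-year incidence per disease — the
order of magnitude of a "common" chronic disease.  There is no
informative censoring, no competing risk, and each disease is simulated
independently given the shared biomarkers; co-risk between diseases
arises only through shared profiles, matching the per-disease modeling
downstream.  Covariate effects enter additively with user-set
coefficients; age may act through a polynomial (default mildly
quadratic) so the spline adjustment has curvature to absorb.

**EHR table.** Generated from the cluster labels alone, not from the
survival cohort — mirroring that the co-occurrence cohort is
independent.  Each subject draws one latent binary susceptibility per
cluster; diseases of a cluster are conditionally independent Bernoulli
given it.  The two conditional probabilities and the susceptible
fraction q are solved numerically (q from a fixed ladder 0.5…0.02,
smallest distortion first; then Brent's method) so that every disease
has exactly the requested marginal prevalence and every same-cluster
pair exactly the requested marginal odds ratio; cross-cluster pairs are
independent by construction.  Combinations whose implied probabilities
leave (0, 1) are rejected.

What this generator does *not* emulate: realistic marginal biomarker
distributions, ICD code semantics, informative censoring, medication
confounding, or time-varying biomarkers.  Passing recovery tests on it
shows the estimators are correct under the model's assumptions — not
that those assumptions hold in any real cohort.

## Hazard ensembles

One ridge-penalized Cox fit per penalty (default 20 evenly spaced values
in [0.01, 0.2]; the range is the analysis's convention, the count a
package default) on a 70/30 split stratified by event status, so rare
diseases keep events in both halves.  Held-out Harrell C-indices become
ensemble weights W_i = c_i / Σc_j; weights are applied to β (log-HR) and
exponentiated once.  Averaging on the log scale keeps hazard ratios
positive and treats protective and risk effects symmetrically; averaging
HRs directly would bias the ensemble above 1.  Raw c_i (not c_i − 0.5)
is used in the weights, which makes near-random models down-weighted
only mildly — documented behavior, not second-guessed.

z-scaling parameters and the age-spline knots (degree 4, interior knots
at training-age quintiles) are estimated on the training split and
re-applied to the test split, avoiding leakage.  Correlated-biomarker
pruning is a greedy pass in input column order — the documented,
deterministic tie-break.  Ties in C-index pairs count 0.5; comparability
follows the standard censored-pairs (Harrell) definition.  Penalties
whose fit fails to converge are dropped with a warning; a disease errors
only when every penalty fails.  Diseases below the incidence threshold
(default 50 cases at synthetic scale; the analysis convention of 2000
applies to ~500k cohorts) are excluded and listed.

## Similarity space

Correlations are computed between biomarker-only profiles on the log-HR
scale (symmetry around 0).  Fixed covariates are always excluded so
similarity cannot arise purely through demographic structure.

The permutation null shuffles entries **within each disease row**: a
disease keeps its multiset of effect sizes but loses biomarker identity.
This is the most conservative null that preserves per-disease effect
distributions; a whole-matrix shuffle is available behind a flag.  The
returned tail probability comes with two intervals: a Wilson binomial CI
over all pair indicators, and a replicate-level CI computed from
per-permutation tail fractions.  The replicate CI is the honest one —
pair correlations within one permutation share rows, so the binomial CI
undercovers — and it is what the calibration tests use (checked against
the exact t-transform null for the Pearson correlation of independent
normal vectors).

The partial-correlation network treats diseases as variables and the
biomarker dimensions as observations (standardized per disease), with
the graphical-lasso penalty chosen by 5-fold cross-validation over
biomarker dimensions.  On convergence failure the fit retries along a
damped (stronger-penalty) path.  Precision is converted to partial
correlations, the diagonal reported as 0, and edges with |value| ≤ 0.1
dropped from the edge list while the full matrix is retained.

## Cluster atlas

UMAP (Euclidean metric on log-HR rows, fixed seed, 2 components)
followed by DBSCAN, with hyper-parameters chosen by exhaustive grid
search.  Default grids: n_neighbors ∈ {5, 10, 15, 30}, min_dist ∈
{0, 0.1, 0.25, 0.5}; eps ∈ {0.1 … 1.0 step 0.1}, min_samples ∈ {2, 3, 5}.
Noise-labeled diseases are excluded from silhouette/CH/DB computation so
legitimate outlier detection is not penalized — but the *selection*
criterion is the silhouette multiplied by the non-noise fraction.
Maximizing the noise-excluded silhouette alone turned out to be
degenerate: a small eps that keeps a few tight fragments and discards
most diseases as noise scores near 1 while recovering almost nothing of
the planted structure (observed: silhouette 0.99 with adjusted Rand
index 0.13).  The scaled criterion restores exact archetype recovery
while reported quality scores remain the raw values.  Ties break by
higher Calinski-Harabasz, then lower Davies-Bouldin, then grid order;
grid points yielding fewer than two clusters score −∞.  Silhouette is
computed in the 2D embedding (where the clustering operates); input-space
scoring is a one-line change and both are recorded in the grid log.

## Comorbidity models

Per-disease lasso-logistic regressions (liblinear, inverse-penalty grid
10⁻³–10 on a log scale) with the penalty chosen by 5-fold stratified
cross-validated log-loss and refit on all subjects.  Coefficients are
penalized log-odds; 0.1 ≈ log(1.1) is the operational comorbidity
cutoff, and 0.5 the profile-similarity cutoff, used by
`comorbid_given_similar`.  An unordered pair counts comorbid when either
directed coefficient clears the cutoff (direction reconciliation by
max).  Optional covariates (age through the same spline basis) are
adjusted for but excluded from the association matrix.  The matrix is
directed and never symmetrized; symmetry emerges only statistically.

## Cluster validation

The τ grid defaults to the sorted unique positive pair strengths, which
evaluates the TMR step function exactly.  Undefined points (no pairs
above τ) are carried as explicit gaps and bridged by omission in the
trapezoidal AUC; the AUC keeps τ·TMR units and is deliberately not
normalized by the τ range.  Noise-labeled diseases are excluded from the
pair universe (a flag can instead count them as automatic non-matches).

The random baseline re-runs embedding and clustering on permuted hazard
matrices with the already-chosen hyper-parameters (a flag enables full
re-optimization per replicate).  The default permutation scheme reorders
**whole profiles across diseases** rather than shuffling entries within
rows.  The within-row scheme was implemented and measured first: it
destroys the geometry of the profile cloud, so the permuted re-clustering
systematically changes granularity — typically one diffuse blob or mostly
noise — and the baseline then measures cluster-size mismatch instead of
cluster/comorbidity alignment (under a null co-occurrence table the score
is biased to ~0.2 instead of 1, and replicates are frequently undefined).
Reordering profiles preserves the set of profiles, hence the number and
sizes of discovered clusters, and randomizes only which disease carries
which profile; under a null EHR the score's replicate interval then
covers 1, and with genuinely aligned structure it sits far above 1.
Entry-level schemes remain available via `scheme=`.  Replicates with
fewer than two defined TMR points are resampled (logged), and the run
errors only if a replicate keeps failing.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is a pure function
of its arguments.  The reference checks use: recovery of planted Cox
coefficients at n = 20 000 subjects and 10 biomarkers with a 5-point
penalty grid; null calibration at n = 3 000 over repeated seeds;
archetype recovery with 40 diseases over the default grids; the
end-to-end validation score with 24 diseases, 3 000 EHR subjects,
within-cluster odds ratio 4 and 8 baseline replicates.  These sizes were
chosen so a full run completes in minutes on one CPU while keeping
Monte-Carlo error far from each check's decision boundary.

## Known limitations

- Only Ridge-penalized Cox models are implemented (the ensemble's
  selection study favored them); no L1 survival variant, competing
  risks, time-varying covariates, or missing-data handling.
- The graphical lasso requires more biomarker dimensions than diseases
  for a well-conditioned fit; with many diseases and few biomarkers the
  CV penalty grows and the network gets conservative.
- UMAP determinism holds for a fixed seed and library version; embeddings
  are not comparable across versions.
- The validation score is a ratio of AUC estimates; with few baseline
  replicates its spread is wide, and the replicate interval — not the
  point estimate — is the honest summary under weak structure.
- No survey weighting or ICD-code harmonization: disease labels are
  synthetic identifiers throughout.
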