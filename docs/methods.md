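# Methods

## Overview

`gbmdecon` implements an absolute-quantification analysis of bulk
glioblastoma (GBM) transcriptomes.  The central assumption is a linear
mixing model: in linear intensity space, the expression profile of a bulk
tumour is a convex combination of pure reference profiles —

    y  =  B f + ε,      f ≥ 0,  Σ_j f_j = 1,

where the columns of the signature matrix `B` are mean profiles of pure
tumour-cell groups (derived from cell-line clustering), a stromal profile,
and lymphoid/myeloid immune subsets.  Because tumour, stromal and immune
compartments together account for every cell in the sample, the estimated
fractions are *absolute* (relative to all cells), not relative to the
immune compartment alone.  Everything downstream — the fraction-based
patient classification and the composite prognostic score — consumes these
fractions.

Expression is stored in log2 scale and converted with `2**x − 1` /
`log2(x + 1)` at the deconvolution boundary, because cell populations
contribute additively to measured intensity in linear space, not in log
space.

## Deconvolution

Two solvers sit behind one interface (`deconv`):

* **nu-SVR path (default).**  The bulk profile and the signature matrix are
  standardised — the profile by its own mean/sd, the signature by the
  *global* mean/sd of the whole matrix.  Global (rather than per-column)
  standardisation matters: since the fractions sum to one, a common affine
  transform of the columns keeps the regression coefficients proportional
  to the fractions, whereas per-column scaling would distort each
  coefficient by its column's sd.  A linear nu-SVR is fitted for
  ν ∈ {0.25, 0.50, 0.75} (C = 1); the fit with smallest reconstruction
  RMSE wins; negative coefficients are clipped to zero and the vector is
  renormalised onto the simplex.  The ε-insensitive support-vector loss
  makes this path robust to genes that violate the mixing model.
* **Simplex QP (oracle/fallback).**  The exact minimiser of ‖y − Bf‖²
  subject to f ≥ 0, Σf = 1 (a strictly convex quadratic program, solved by
  SLSQP with an analytic gradient and verified in the tests against an
  independent accelerated projected-gradient solver).  It is the
  config-selectable exact solver and the fallback whenever the SVR
  degenerates (no positive coefficient).

Whether the sum-to-one constraint belongs inside the SVR optimisation or
is applied post hoc is a genuinely open design point; we pin the post-hoc
interpretation (clip + renormalise, as in the CIBERSORT lineage) and keep
the exact in-optimisation variant available as the QP solver, so the choice
is isolated behind one interface.  On noiseless mixtures the two agree to
~1e-3; the QP is exact to 1e-6.

Per-sample diagnostics (RMSE, Pearson r of the reconstruction, chosen ν,
solver used) are recorded.  Cohort deconvolution requires at least 50% of
the signature genes to be present; mixture genes absent from the signature
are dropped, never imputed.

## Signature construction

Cell-line groups come from HCPC: centred (not gene-scaled) PCA, 5
components by default, Ward linkage on Euclidean distance over the scores,
and the cut chosen automatically as the k ∈ 2..k_max maximising
Δ(k)/Δ(k+1) with Δ(k) = W(k−1) − W(k), the relative loss of within-cluster
inertia.

Group markers are found with a moderated one-vs-rest t-test: the pooled
two-sample variance of each gene is shrunk toward a scaled inverse-χ²
prior whose degrees of freedom and scale are moment-matched on the
distribution of log sample variances (trigamma inversion by Newton
iteration); p-values are two-sided on the moderated t with augmented
degrees of freedom, and Benjamini–Hochberg adjusted within each contrast.
Zero-variance genes are kept with t = 0, p = 1 so gene indices stay
aligned.  Setting the prior df to 0 recovers the ordinary pooled t exactly;
a flag switches to Welch's t for oracle comparison.

Markers are genes with FDR < 0.05 and positive log fold-change, ranked by
p then |logFC|, capped at top_g = 50 per group (the cap keeps the basis
well-conditioned; condition numbers on the synthetic panel are < 5).  A
gene passing in several groups is assigned to the group with the larger
|logFC| so marker lists are disjoint.  Immune/stromal references come as
one profile per population, so their markers are the top_g genes with the
largest log-ratio over the mean of the other populations.  The basis is
the per-population linear-scale mean over the union of all marker genes,
with role tags (tumour-group / stromal / lymphoid / myeloid).

## Patient classification and transfer

Discovery patients are clustered on their **tumour-group fraction columns
only** (the immune columns enter the survival model instead — including
them here would conflate the two classifications); Ward linkage, number of
clusters chosen in 2..6 by the gap statistic: Gap(k) = mean_b log W*_kb −
log W_k with B = 50 uniform reference datasets over the data's bounding
box, choosing the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1} (the
one-standard-error rule).  Validation patients receive labels from a
500-tree random forest trained on the discovery fractions.

For transferring the published four-subtype molecular classification the
package provides nearest shrunken centroids (PAM): standardised centroid
deviations d_kg = (x̄_kg − x̄_g)/(m_k (s_g + s0)), m_k = √(1/n_k − 1/n),
s0 = median(s_g), soft-thresholded at Δ, with classification by
standardised squared distance minus 2·log prior; Δ is chosen by stratified
10-fold cross-validated accuracy (smallest Δ on ties).  The discriminating
gene list is an input file, never embedded data.

## Survival modelling

Overall survival is administratively censored at 24 months and
disease-free survival at 12, so late follow-up differences between cohorts
cannot drive the models.  Kaplan–Meier curves, log-rank tests and
univariate Cox fits (Efron ties, the convention of the R survival
ecosystem) back the screens; monotone-likelihood separation is flagged and
refitted with a small ridge penalty.  The immune screen tests every
fraction as a continuous covariate, overall and within each patient class
(classes under 10 samples are skipped and logged), at two-sided 0.05
without multiplicity correction — deliberately liberal, as a screen.

The composite model is an L1-penalised Cox regression on the design
[class dummies | immune fractions | dummy×fraction interactions], with the
alphabetically first class as reference.  The classification dummies carry
penalty factor 0 — *forced*, so the LASSO can never remove the
classification — and all other columns penalty factor 1.  Covariates are
standardised internally and the standardisation is frozen in the model.
Lambda is chosen at the minimum of the 5-fold cross-validated
partial-likelihood deviance (Verweij–van Houwelingen: dev = −2·[ℓ_full(β_{−i})
− ℓ_{−i}(β_{−i})], Breslow ties for the CV likelihood), deterministically
given the seed; CV-minimum rather than 1-SE because the model is reported,
not pruned further.  When every column is forced the fit reduces to an
unpenalised Cox model.

Risk groups: the linear predictor is split at the **training median**
(ties to "low"); the threshold, coefficients and standardisation are
frozen and reused verbatim on validation cohorts — no re-thresholding.
The three-tier score refits a Cox model on (linear predictor, age) —
re-estimating the lp coefficient rather than fixing it at 1, the more
standard composite construction — and cuts its linear predictor at the
training Q1/Q3.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis assumes:

* a reference panel of 129 cell lines (3 groups × 43) over 2,000 genes;
  each group owns a disjoint block of n_genes/(2k) markers shifted by
  +3 log2 units over a Uniform(3, 8) baseline with N(0, 0.5) noise;
* ten pure immune/stromal profiles with disjoint marker blocks (2% of
  genes each, +4 log2), placed at the opposite end of the gene list from
  the tumour blocks;
* bulk cohorts of 200 (discovery) and 100 (validation) tumours mixed in
  linear scale as B·f + truncated Gaussian noise (sd = 5% of the mean
  signal), f ~ Dirichlet with mass 24 on a randomly drawn dominant tumour
  group, 3 on the other tumour groups and 1 on each immune/stromal
  population — so most tumours carry under 10% immune cells, the
  infiltration regime the method must resolve;
* exponential survival (baseline 0.06/month, exponential censoring
  0.01/month) with log-hazard 3.0 per unit of the third tumour-group
  fraction, 10.0 per unit Treg fraction (immune fractions live below 0.1,
  hence the large per-unit coefficient) and 0.023 per year of age.  The
  group effect size was fixed by a design power computation: at the
  validation cohort's ~85 events a between-group log-HR near 1.5 gives
  noncentrality > 20, i.e. ~99% power for the planted structure to be
  detectable at log-rank p < 0.01 — cohorts one-fifth the size of a real
  discovery cohort need a proportionally stronger planted effect.

Deliberately not emulated: probe-level array structure, probe→symbol
multiplicity, platform-specific intensity distributions, heavy-tailed or
intensity-dependent noise (the Gaussian-in-linear-scale choice is a
stand-in; real array noise is closer to log-normal), within-population
expression heterogeneity of immune cells, correlated marker programs
shared between populations, and non-proportional hazards.  Passing tests
therefore demonstrate correctness of the machinery under the model's own
assumptions — identifiability, constraint satisfaction, recovery,
transferability — not performance on real arrays, where marker overlap
and reference mismatch are the dominant error sources.

## Numerical choices and degenerate inputs

* QP solved at ftol 1e-16 with analytic gradient, inputs pre-scaled by the
  mean absolute signature entry for conditioning; final projection clips
  residual negatives (≤1e-12) and renormalises.
* Simplex contract is enforced to 1e-6 on every row of every solver path.
* HCPC ties in the inertia ratio resolve to the smaller k; cluster labels
  are renumbered 1..k by first appearance, so partitions are deterministic
  and order-stable.
* Gap-statistic reference W values are floored at 1e-300 before logging.
* NSC ties in the discriminant resolve to the lowest class index and are
  flagged.
* Zero-variance genes: kept with t = 0, p = 1 (never silently dropped).
* Batch correction (ComBat-style parametric empirical Bayes, location and
  scale) refuses singleton batches; the location-only mode centres batch
  means exactly (no shrinkage), because the exact-alignment contract and
  EB shrinkage are mutually exclusive.
* All generators and stochastic stages are pure functions of an explicit
  seed; the pipeline records every seed in its manifest.

## Problem sizes

The shipped analyses and checks run at: 129 reference profiles × 2,000
genes; 200 + 100 bulk tumours; 1,000 fuzzed profiles for the constraint
check; 20 seeds for cluster-number and Cox recovery; 10 seeds × 400
patients for LASSO selection.  These sizes were chosen so every result is
stable under reseeding while the whole analysis remains a desk-scale
computation.

## Known limitations

* The nu-SVR path's constraint handling is post hoc; fractions near the
  simplex boundary are biased toward the interior by at most ~1e-3 on
  clean data.
* The gap statistic with a bounding-box reference prefers small k on
  elongated single clusters; the patient-clustering range is fixed to 2..6
  by design, so k = 1 ("no structure") is never reported.
* The moderated-t prior fit assumes a common variance prior across genes;
  strongly bimodal variance distributions would be better served by a
  mixture prior.
* Univariate screens are unadjusted for multiplicity by design and should
  be read as screens, not discoveries.
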