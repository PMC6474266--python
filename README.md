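# gbmdecon

Absolute deconvolution of bulk glioblastoma (GBM) transcriptomes into
tumour-cell, stromal and immune fractions — and a prognostic score built
from them.

## The problem

Bulk GBM expression profiles mix signal from malignant cells with signal
from stroma and infiltrating immune cells, so classifications fitted on
bulk transcriptomes confound the tumour cell's identity with its
microenvironment.  This package separates the two.  It models a bulk
profile, in linear intensity space, as a convex mixture of pure reference
profiles:

    y = B f + ε,    f ≥ 0,  Σ_j f_j = 1,

where the columns of the signature matrix **B** are pure tumour-cell
groups (from clustering cell-line transcriptomes), a stromal profile and
lymphoid/myeloid immune subsets.  Because the references span *all* cell
compartments, the fractions **f** are absolute — Treg = 0.03 means 3% of
all cells in the sample — not proportions of the immune compartment only.
The regression engine is a constrained linear nu-SVR (support-vector loss
for robustness to genes violating the mixture model; ν chosen from
{0.25, 0.5, 0.75} by reconstruction RMSE; coefficients clipped and
renormalised onto the simplex), with an exact simplex-constrained
least-squares QP available as alternative solver and verification oracle.

On top of the fractions the package builds the full analysis: cell-line
clustering (HCPC: Ward on principal components, automatic k by highest
relative inertia loss), moderated-t signatures, patient classification on
tumour-group fractions (Ward + gap statistic), random-forest label
transfer to a validation cohort, nearest-shrunken-centroid subtype calls,
univariate Cox screens of every immune fraction, and a LASSO-Cox
composite score in which the patient classification is *forced* (penalty
factor 0) and immune fractions and interactions are selected.  Risk
groups use the training-median threshold, frozen and reused verbatim on
validation; a final (linear predictor, age) Cox fit yields a three-tier
score cut at the training quartiles.

A first-class synthetic-data module generates reference panels, bulk
cohorts and survival outcomes with known ground truth, so every stage is
verifiable end-to-end without any data download.  See
[docs/methods.md](docs/methods.md) for models, assumptions and parameter
choices.

## Worked example

The `analysis/` scripts run the whole study on a synthetic two-cohort
dataset (129 cell lines, 200 discovery + 100 validation tumours):

```bash
python analysis/01_synthesize_study.py
python analysis/02_cluster_cell_lines.py
python analysis/03_build_signature.py
python analysis/04_deconvolve_cohorts.py
python analysis/05_classify_patients.py
python analysis/06_survival_model.py
```

Selected output (seed 1):

```
HCPC chose k = 3 cell-line groups
adjusted Rand index vs planted groups: 1.000
signature matrix: 641 genes x 13 populations, condition number 3.2
discovery: 200 tumours deconvolved; Pearson r vs true fractions 1.0000
  mean compartments: tumour 0.92, stromal 0.01, lymphoid 0.037,
  myeloid 0.032; 80% of tumours have <10% immune cells
gap statistic chose k = 3 patient classes
discovery: adjusted Rand index vs planted dominant group = 1.000
validation: adjusted Rand index vs planted dominant group = 1.000
immune populations associated with OS (p<0.05, discovery): ['Treg', 'Th2']
LASSO kept 7 variables (classification forced)
discovery: median OS by risk group (months) {'high': 1.8, 'low': 7.7};
  log-rank chi2 = 36.1, p = 1.9e-09 (frozen discovery threshold)
validation: median OS by risk group (months) {'high': 2.6, 'low': 7.1};
  log-rank chi2 = 8.8, p = 0.003 (frozen discovery threshold)
```

Reading this: the cell-line panel's three planted groups are recovered
exactly; deconvolved fractions track the true mixing proportions
(r ≈ 1.0) and reproduce the low-infiltration regime (most tumours under
10% immune cells); patients cluster by their dominant tumour-cell group
in both cohorts; the Cox screen flags the population carrying the planted
hazard (Treg); and the composite risk score — fitted only on the
discovery cohort, with its median threshold frozen — separates survival
in *both* cohorts, which is the transferability claim the pipeline exists
to test.

The same pipeline runs from a single config on any conforming inputs:

```bash
gbmdecon synthesize --outdir study --seed 1
gbmdecon run --config study/config.yaml --outdir out
```

or stage by stage via the `signature`, `deconv`, `cluster`, `classify`
and `survival` subcommands.

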