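# bcmeta

Integrative multi-study microarray meta-analysis for bladder-cancer (BCa)
biomarker discovery — a tested, reusable re-implementation of the full
tissue-to-signature workflow: cross-platform harmonization, covariate-adjusted
moderated differential expression with classifier-driven threshold selection,
dual network-based hub-gene identification, consensus weighted co-expression
modules, biofluid / therapy-response screens, and penalized Cox risk
signatures with survival-based evaluation.

It is aimed at computational biologists who need the *pipeline* (the
statistics and their contracts) rather than any one cohort: a synthetic-data
module generates every input — multi-study expression with batch effects,
survival and ordinal-response cohorts, interaction graphs with planted
structure — with known ground truth, so each stage ships with
parameter-recovery and null-calibration tests.

## The statistics at the core

**Harmonization.** Probes collapse to gene symbols (mean of uniquely
annotated probes). Arrays are screened on three quality metrics (mean
inter-array distance, KS of a sample's distribution vs the pooled rest, mean
|M| vs a median pseudo-reference), flagged by the Tukey upper fence, and
removed when ≥ 2 of 3 metrics flag. Each sample is Z-scored over its genes,

  Z = (I_G − Ī) / σ,

and studies are merged over their common gene set with study of origin kept
as a covariate. Known batches can be adjusted with a parametric
empirical-Bayes location/scale model.

**Differential expression.** Per gene, least squares on
`intercept + group + study`; residual variances shrink toward a scaled-F
prior fit by method of moments on log s², giving moderated t-statistics with
augmented degrees of freedom; p-values are BH-adjusted. Each effect is also
reported as a *corrected* log2 fold change — the effect divided by the
across-gene SD of all effects — and a grid of |corrected FC| cutoffs
(1.0–2.0, step 0.1) is scanned with a linear SVM (10 stratified 90:10
splits); the AUC-maximizing cutoff defines the DEG set.

**Network hubs.** A STRING-style interaction graph (combined score ≥ 0.4) is
ranked by ten topological centralities (MCC, MNC, Degree, EPC, BottleNeck,
EcCentricity, Closeness, Radiality, Betweenness, Stress). Robust rank
aggregation scores each node by the minimum Beta order-statistic tail of its
normalized ranks, Bonferroni-corrected (hubs: p < 0.01). Independently,
MCODE detects dense clusters (k-core vertex weighting, seeded growth,
haircut) scored 2E/(n−1) and filtered at ≥ 7. The PPI hub list is the
intersection.

**Consensus co-expression.** Per dataset (> 20 samples), an unsigned network
|cor|^β at a soft power chosen for scale-free fit (R² ≥ 0.77, median
connectivity < 30) becomes a topological overlap matrix; per-dataset TOMs
are quantile-scaled and combined by an elementwise minimum, clustered into
modules (min size 30, merge height 0.25). Module–trait consensus follows a
sign-consistency rule (signed minimum |cor|, else 0); per-gene module
membership (MM) and gene significance (GS) combine across datasets into
√n-weighted meta-Z scores; hubs are genes in the same outer quartile of both.
Key hub genes = key-module hubs ∩ PPI hubs.

**Signatures.** Candidate genes pass a univariate Cox screen (Breslow
partial likelihood, Newton–Raphson), then iterated 10-fold cross-validated
LASSO-Cox (λ by the cross-validated Harrell C of pooled held-out linear
predictors; genes kept when nonzero in ≥ 75% of iterations), then a joint
Cox fit whose coefficients define a prognostic index PI = Σ cᵢxᵢ (the
predictive variant PDI takes |Σ cᵢxᵢ|). Evaluation: median-split
Kaplan–Meier with the log-rank test, time-dependent ROC at 1/3/5/10 years
(cumulative-case / dynamic-control with KM censoring adjustment), and
Harrell's C-index. A fixed gene panel's diagnostic value is evaluated with
repeated stratified cross-validation AUC.

## Worked example

```python
from bcmeta import synthetic as syn, de, survival as sv
from bcmeta.harmonize import merge_studies, zscore_transform

cfg = syn.SimConfig(seed=7)                     # 3 studies, 2x(30,30) ... defaults
studies, truth = syn.simulate_study_collection(cfg)
merged = merge_studies([zscore_transform(s) for s in studies])

res  = de.differential_expression(merged)
scan = de.select_deg_threshold(res, merged, seed=7)
print(scan.selected_threshold, len(scan.selected_genes))
# 1.0 144   <- all 44 planted differential genes present in the merged
#            matrix are inside the selected DEG set

cohort, _ = syn.simulate_survival_cohort(syn.SimConfig(
    seed=7, survival=syn.SurvivalSimConfig(
        n_patients=300, n_genes=61,
        log_hr={"G0001": 0.8, "G0002": -0.9, "G0003": 0.8})))
sel, _ = sv.lasso_cox_select(cohort, list(cohort.expression.columns),
                             iters=20, seed=7)
print(sel)                      # ['G0001', 'G0002', 'G0003']  (exactly the planted genes)
fit, model = sv.cox_multivariate(cohort, sel)
scores = sv.risk_index(model, cohort.expression)
split  = sv.median_split_km_logrank(scores, cohort)
roc    = sv.time_dependent_roc(scores, cohort, horizons=(1, 3, 5))
```

This prints a fitted signature close to the planted log-hazard ratios
(0.722, −0.916, 0.812 vs planted 0.8, −0.9, 0.8), a log-rank p of 1.2e−26
with hazard ratio 4.86 between median-split risk groups, C-index 0.776, and
time-dependent AUCs {1y: 0.804, 3y: 0.835, 5y: 0.856} — i.e. the planted
prognostic structure is recovered end to end.

A CLI mirrors the stages (`bcmeta simulate | harmonize | de | hubs | wgcna |
fluids | prognostic | predictive | panel | run-all`); see `bcmeta --help`.

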