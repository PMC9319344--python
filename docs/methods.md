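# Methods

This note documents the models, the choices made where the procedure was
genuinely open, the synthetic generators and what passing tests do and do
not establish, and known limitations.

## Harmonization

Array quality control uses three per-sample metrics: (i) mean Euclidean
distance to all other arrays, (ii) the Kolmogorov–Smirnov statistic of the
sample's value distribution against the pooled distribution of the remaining
samples, and (iii) the mean |M| of the sample against the gene-wise median
pseudo-reference (M = sample − reference). Each metric flags samples above
the Tukey upper fence (Q3 + 1.5·IQR); an array is an outlier when flagged on
at least two metrics. These statistics are deterministic stand-ins for the
heatmap/boxplot/MA-plot detectors commonly used interactively; they are
close in spirit but are not claimed to reproduce any particular interactive
run. Studies with fewer than four samples skip QC with a warning — the
fences are meaningless at that size.

Per-sample Z-scoring uses the n−1 SD denominator. Merging intersects gene
panels and then **re-standardizes each column over the intersected genes**,
so every merged sample has mean 0 / SD 1 exactly; z-scores computed on a
study's full panel would not retain that property after intersection.

Known-batch adjustment is the parametric empirical-Bayes location/scale
model: gene-wise standardization against a size-weighted grand mean and
pooled variance; per-batch, per-gene location (normal prior) and scale
(inverse-gamma prior, moment-matched) effects shrunk by iterated EB updates
(tolerance 1e−8, ≤ 100 iterations); back-transformation. A single batch
returns the input unchanged; singleton batches are an error because their
scale effect is not estimable. Estimation of *unknown* batch structure
(surrogate variables) is out of scope — the synthetic data always carries
batch labels, and the merged-matrix analysis handles batches as a model
covariate instead.

## Differential expression

The per-gene model is ordinary least squares on
`intercept + case/control + study indicators` (study effects as fixed
offsets). Variance moderation follows the scaled-F hierarchy
s² ~ s0²·F(d_res, d0): method-of-moments on log s² via the digamma/trigamma
identities, with the trigamma inverse solved by Newton iteration. When the
observed spread of log s² does not exceed its sampling expectation, d0 is
infinite and every variance shrinks to the geometric mean of the observed
s² — the degenerate case is defined so that identical s² reproduce the
ordinary t exactly. Moderated t has d0 + d_res degrees of freedom (normal
when infinite).

The corrected fold change divides each gene's group effect by **one global
scalar**: the across-gene SD (n−1) of all effects. The alternative —
recomputing σ per gene subset — was rejected because it would make a gene's
"fold change" depend on which other genes are in the matrix at filter time;
the global scalar makes the statistic scale-invariant and stable.

The threshold scan trains a linear margin classifier (LinearSVC, C = 1) on
the genes surviving `p_adj < 0.01` and `|corrected FC| ≥ τ` for
τ ∈ {1.0, …, 2.0}. The evaluation scheme is 10 repeated stratified 90:10
splits with averaged AUC/sensitivity/specificity (a plain stratified
10-fold option exists); the case class is positive, sensitivity is its
recall at the zero decision threshold. AUC ties break toward the smaller τ —
the more inclusive gene set. A kernel was deliberately not tuned: the linear
machine is deterministic, fast, and the scan compares gene *sets*, not
kernels.

## Network hubs

The ten centralities follow the cytoHubba descriptions; where those leave
freedom the definitions are fixed as:

- MCC(v) = Σ over maximal cliques containing v of (|C|−1)! (exact clique
  enumeration).
- MNC(v) = size of the largest connected component of the open neighborhood.
- EPC(v) = mean size of v's component over R = 1000 seeded edge-percolation
  realizations with retention 0.5 (both configurable). EPC is the one
  stochastic ranking; it is seeded and excluded from exact-equality tests.
- BottleNeck(v) = number of rooted shortest-path structures (one per root)
  in which v lies on more than |reachable|/4 of the root-to-leaf shortest
  paths. The count uses the full shortest-path DAG per root rather than one
  arbitrary BFS tree, which makes the score invariant under node relabeling;
  a single tree would depend on neighbor iteration order.
- EcCentricity(v) = 1/eccentricity within v's component.
- Closeness(v) = Σ 1/d(v,w) (harmonic form; disconnected pairs contribute 0).
- Radiality(v) = Σ_w (diam + 1 − d(v,w)) / (n−1) per connected component.
- Stress(v) = number of shortest paths through v (each unordered pair once).
- Betweenness: standard fraction form, unnormalized.

RRA: normalized ranks r = rank/|universe| (absent items r = 1), score
rho = min_k P(Beta(k, m−k+1) ≤ r_(k)), p = min(1, m·rho). For a discrete
rank universe the Beta tails coincide exactly with the permutation null of
the order statistics, which is what the Monte-Carlo oracle test checks.

MCODE: vertex weight = highest-k-core density of the closed neighborhood ×
core number; complexes grow breadth-first from the highest-weight unseen
seed, admitting unseen neighbors with weight ≥ (1 − node score cutoff) ×
seed weight, to max depth 100; complexes lacking a 2-core are discarded
("k-score = 2" read as a 2-core requirement); haircut removes
singly-connected members once; score = 2E/(n−1), retained at ≥ 7. The
"fluff" stage is omitted (haircut-only runs do not use it). Clusters are
node-disjoint by construction.

## Consensus co-expression

Unsigned adjacency |cor|^β (Pearson; trait coded case = 1 / control = 0).
Soft-power selection bins connectivity into 10 equal-width bins and
regresses log10 frequency on log10 mean connectivity; the fit index is
−sign(slope)·R². Two qualification criteria follow the published settings
(fit ≥ 0.77, median k < 30) plus one guard added here: powers whose median
connectivity falls below 1 never qualify, because in that degenerate regime
(k → 0) the log-log fit becomes spuriously linear even on i.i.d. noise.

TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), diagonal 1.
Per-dataset TOMs are scaled to the first dataset's 95th percentile by a
power transform (keeps [0,1]) and combined by elementwise minimum.

Module detection replaces the dynamic hybrid tree cut with a fixed-height
cut of the average-linkage tree at the median merge height, followed by two
repair stages: (1) every raw cluster with ≥ 3 genes takes part in iterative
eigengene merging (merge when the minimum-across-datasets ME correlation
exceeds 1 − 0.25), and only then does the minimum-size rule (30) send small
leftovers to grey; (2) grey genes whose sign-consistent consensus kME
reaches 0.5 join their best module. The low cut + repair design is
deliberate: an over-split module is reassembled by stages (1)–(2), whereas
an over-merged one cannot be separated afterwards. `deepSplit` is therefore
inert; module *recovery* (adjusted Rand index against planted factors), not
label identity with any reference run, is the tested contract.

Eigengenes are the leading right singular vector of the standardized module
matrix, sign-oriented positively against the module mean profile. The
module–trait consensus is the signed minimum absolute correlation when all
datasets agree in sign, zero otherwise (p: maximum across datasets, or 1).
MM and GS correlations combine across datasets as Stouffer meta-Z with √n
weights (Fisher z·√(n−3) per dataset; n ≤ 3 skipped). The weighting scheme
is a choice — √n Stouffer is the standard consensus-WGCNA convention.
Module hubs require MM and GS meta-Z jointly in the top quartile or jointly
in the bottom quartile of their module (boundaries inclusive). Under this
literal rule a module whose MM and GS are anti-aligned (e.g. a
disease-downregulated module with positively-oriented eigengene) can yield
no hubs at all — that is faithful behavior, and empty per-module entries are
expected output, not errors.

## Screens

Biofluid and response screens use the two-sided Wilcoxon rank-sum test:
exact when the smaller group has ≤ 8 observations and no ties, otherwise the
normal approximation with tie and continuity correction (scipy's `auto`
policy implements exactly this rule). No across-gene multiplicity correction
is applied — the screens filter at raw p < 0.05, which is deliberately
liberal and documented as such. The response cohort yields the three
pairwise contrasts plus no-vs-(partial ∪ complete).

## Survival signatures

Cox fits maximize the Breslow-tie partial likelihood by Newton–Raphson with
step halving; Wald CIs and p-values. Breslow is the simplest consistent tie
contract, and on the tie-free synthetic data it agrees with Efron (the
lifelines cross-check in the tests). Non-convergence and separation are
errors: a fit whose largest |coefficient| exceeds 15 at convergence (or 50
mid-iteration) is declared monotone-likelihood.

LASSO-Cox selection: a 100-point λ path (4 decades below the data-driven
maximum) is fit once on the standardized full data; each of the (default)
100 iterations re-randomizes the 10-fold assignment, fits the path per fold
and scores every λ by the Harrell concordance of the pooled held-out linear
predictors. λ is the *sparsest* value attaining the maximum concordance,
and an iteration selects the empty model unless the best concordance
exceeds 0.5 by two null standard errors (≈ 1/√(12·events)) — the penalized
path never contains the exactly-null solution, so the null model is added
explicitly as a candidate. Genes nonzero in ≥ 75% of iterations are
selected. The concordance criterion (rather than minimum CV deviance /
"lambda.min") is the package's design choice: held-out deviance minima
systematically carry several noise genes into the selection, while the
concordance rule recovers planted prognostic genes with no false positives
and returns empty selections under pure-noise inputs; minimum-deviance
selection remains available via `fit_measure="deviance"`.

The prognostic index is PI = Σ cᵢxᵢ with the multivariate Cox coefficients.
The predictive index applies an absolute value, PDI = |Σ cᵢxᵢ|, exactly as
the published formula prints it, even though this makes the score
non-monotone in the linear predictor — the literal contract is implemented
and flagged here.

Median split: high risk = score strictly above the median; ties go to the
low-risk group (deterministic). Log-rank via lifelines; the between-group
hazard ratio comes from a one-covariate Cox fit on the group indicator.
Time-dependent ROC is the cumulative-case/dynamic-control estimator with
Kaplan–Meier censoring adjustment: P(X > c, T > t) = P(X > c) ·
KM_{X>c}(t), sensitivity/specificity from the joint law, trapezoidal AUC
over the unique score cutpoints; without censoring it reduces exactly to the
empirical Mann–Whitney AUC of cases (T ≤ t) versus controls (T > t), which
the oracle test asserts to 1e−10. Harrell's C counts a pair as usable when
the earlier observed time is an event and the times differ; tied scores
earn 0.5. Horizons are expressed in the cohort's own time unit; the config
carries a unit declaration because public cohorts mix months and years.

## Diagnostics panel

Fixed-panel evaluation is repeated stratified k-fold CV (5×10 per dataset, a
single 10-fold pass for the merged matrix) with the same linear margin
classifier as the DE threshold scan (one classifier family throughout, by
design). The 95% CI is a percentile bootstrap (2000 resamples) over the fold
AUCs. Fold AUCs are reported individually; pooled-prediction ROC
coordinates can be derived from the held-out scores but the fold-AUC mean is
the headline number.

## Synthetic data: what it emulates, and what it does not

Expression is Gaussian on the log2 scale. Per study: baseline gene means
N(7,1); latent module factors (default 4, on 40% of genes, loadings
U(0.7,1)) optionally tilted toward the phenotype (default correlation 0.5);
a signed planted shift (default 1.5 log2 units on 5% of genes, cases only);
per-study-per-gene batch location N(0, 0.5) and error-scale exp(N(0, 0.2))
— exactly the location/scale model the EB batch adjuster assumes; i.i.d.
noise SD 0.5. Default collection: 3 studies of 30 cases + 30 controls,
1000 genes, 80% shared panel with random per-study dropout of the rest, so
the common-gene intersection step is always exercised.

Survival: exponential hazards h0·exp(Σ β_g x_g) (h0 = 0.1, default planted
|log-HR| 0.7–0.9 on 3 of 61 genes — the published key-hub count — with
standard-normal expression); censoring Uniform(0, C) with C solved by
bisection so the expected censoring fraction hits the target (default 0.3).
Response follows a proportional-odds model with thresholds at the
configured base rates (default uniform thirds). Graphs are Erdős–Rényi
(default n = 300, p = 0.01) with planted cliques (default one K9) whose
edge scores (U[0.7,1)) dominate the background (U[0.4,0.7)).

Every generator draws from a child of one master seed through fixed
`SeedSequence` spawn keys, so outputs are byte-reproducible and adding a
generator never perturbs existing ones.

Not emulated: probe-level chemistry and platform preprocessing, heavy-tailed
or intensity-dependent noise, gene–gene correlation outside the factor
model, non-proportional hazards, informative censoring, and real annotation
ambiguity. Passing tests therefore demonstrate correctness of the
*statistics* and recovery under the generating model — not performance on
any real cohort.

## Problem sizes used in the test and acceptance runs

Null calibrations use 200 seeded replicates (2 studies × (10,10) samples ×
200 genes for the DE model; 15 vs 15 × 20 genes for the rank-sum screen;
n = 150 and n = 100 cohorts for Cox and log-rank). Recovery runs use
10 seeds each: 2×(30,30)×400 genes for the planted-shift check, n = 300
with 3 signal genes among 50 (25 LASSO iterations) for selection, 300-gene
two-dataset collections for module recovery, and n = 300×61-gene cohorts
for the end-to-end prognostic chain (10 LASSO iterations). These sizes were
chosen as the smallest at which the quantities being checked are stable;
the library defaults (100 iterations, full grids) remain the published
settings.

## Known limitations

- The QC metrics are principled stand-ins; no claim is made to reproduce any
  interactive arrayQualityMetrics session.
- The fixed-height-cut + repair module detector is simpler than the dynamic
  hybrid cut; highly nested module structure may be partitioned differently
  (the recovery contract, not label identity, is tested).
- EPC and BottleNeck follow published descriptions that leave internals
  open; both are documented approximations (EPC's realization count and
  retention, BottleNeck's DAG-based path counting).
- The Wilcoxon screens are intentionally uncorrected across genes.
- `cox_multivariate` refuses more covariates than events/2 rather than
  regularizing; use the LASSO stage to shrink the candidate set first.
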