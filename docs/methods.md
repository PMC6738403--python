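# Methods

This note documents the models and procedures implemented in `t2dbrain`,
the defaults and why they are set where they are, the numerical choices, and
what the synthetic validation does and does not establish.

## Cohort filtering and matching

Samples are retained when RIN > 6.0 (strict inequality), status is a known
binary T2D indicator, and race falls in the configured set (default
black/white, matching common practice of restricting to the two largest
ancestry groups when sample sizes are small). Controls are then matched to
cases at ratio 2:1.

The distance is a propensity score: logistic regression of status on age,
sex, race, BMI and RIN, with categorical covariates one-hot encoded against
the first level. The assignment minimises the total |score(case) −
score(control)| over all ways of giving each case `ratio` distinct controls;
this is solved exactly by duplicating each case node `ratio` times and
running the Hungarian algorithm, so the result is the global optimum rather
than the order-dependent greedy solution. Samples are sorted by id before
assignment, making ties deterministic. On perfect separation of the logistic
model the matcher falls back to covariate-space Mahalanobis distance (logged
warning; recorded in the cohort's `distance_metric`). Balance is reported as
standardised mean differences and two-sample tests pre- and post-matching; a
zero pooled SD yields SMD 0 when means agree and ±inf otherwise. Matching
with replacement, calipers and full matching are out of scope.

## Surrogate variables

Hidden expression heterogeneity (batch, unmeasured biology) is estimated
from Y = log(K/s + 1), with s the median-of-ratios size factors and
pseudocount 1. Residuals R of Y on the full design (intercept + covariates +
status by default; a flag restricts protection to the covariates only) are
decomposed by SVD and the top `n_sv` right singular vectors are the initial
surrogate variables. For `n_iter` rounds (default 5) each gene receives
weight w_g = 1 − p_g, where p_g is the p-value of the F-test comparing the
full model with and without the current SVs, and the SVD is recomputed on
the row-weighted residuals; `n_iter = 0` is exactly the plain residual SVD.
`n_sv` defaults to 3, an explicit parameter rather than an estimated
dimension — the permutation heuristics used to pick the dimension are
fragile at these sample sizes and the analyses this pipeline reproduces
fixed 3.

Because the residuals are orthogonal to the protected design, the SVs cannot
absorb the status effect (measured |cor| with status is at numerical zero).
Recovery of a planted batch is bounded by the chance collinearity of the
batch with the known covariates (≈ R² of 7 design columns on n samples), so
the acceptance check reports a median over cohorts. A genuine limitation:
any latent factor not in the design, including real co-expression
structure, is "hidden heterogeneity" to this procedure, so with k strong
module factors and n_sv = 3, up to three module factors are absorbed and
their modules attenuated downstream. On the synthetic demo typically only
one to three of the five planted modules survive residualisation, depending
on the seed; the status-driven module always survives because its status
component is protected.

## Differential expression

NB2 GLM per gene: K_gj ~ NB(μ_gj, α_g), Var = μ + αμ², log μ = xβ + log s_j.
Fitting is IRLS vectorised across all genes (batched 8×8 weighted
least-squares solves), initialised from a log-linear fit on log(K + 0.5),
converged at max |Δβ| < 1e-8 (cap 50 iterations; non-converged genes are
flagged and excluded from testing). Linear predictors are clipped to ±30 on
the log scale for stability.

Dispersions: method-of-moments start; genewise MLE given fitted means by a
global 60-point log-grid search on [1e-8, 30] with two local refinement
passes (~1e-3 accuracy in log α — ample, since shrinkage follows); a robust
(Huber) regression of genewise α on 1/μ gives the trend α_tr(μ) = a1/μ + a0;
the final dispersion is exp of the precision-weighted average of log α̂ and
log α_tr, with likelihood variance approximated by trigamma((n − p)/2) and
prior variance max(observed excess, 0.25). There is no Cox–Reid adjustment
and no outlier re-fitting; on Poisson truth the shrunken dispersions collapse
to ~1e-8 and on NB truth (α = 0.2, n = 100) the genewise MLE is unbiased to
within the acceptance band.

The Wald statistic is β̂/SE on the status coefficient with a two-sided
normal p. Independent filtering scans mean-normalised-count quantile
thresholds θ ∈ {0, 0.01, …, 0.95}, BH-adjusts the surviving genes at each θ,
and keeps the smallest θ attaining the maximal rejection count; genes below
the threshold get undefined padj. Under a global null this argmax selection
is mildly liberal (it can promote a handful of discoveries where plain BH
gives none); the empirical FDR on planted-signal cohorts stays within the
nominal band, which is the operating regime that matters.

The "rlog" used downstream is the shifted log of normalised counts,
Y = log2(K/s + 1): monotone, scale-invariant and approximately homoscedastic
at moderate counts, which is all the clustering and network stages require.
The sample-clustering diagnostic uses correlation distance (1 − Pearson)
with average linkage cut at two clusters and a two-sided Fisher exact test
of cluster × status. The bootstrap subsampling curve re-runs the whole DE
stage on nested case/control subsamples (controls = 2× cases) and reports
the mean ± sd discovery count per size.

## Genomic composition and distance

Biotype and chromosome compositions are proportions over the gene set, with
unannotated genes counted as "unknown" under a warning. Distances are
|TSS_i − TSS_j| for same-chromosome pairs, with the strand-aware TSS (start
on +, end on −) as the default anchor (midpoint and start are selectable and
recorded in output). Genes present in both sets are excluded from
between-set pairs to avoid zero-distance artifacts. The Wilcoxon rank-sum
test uses exact enumeration when n_x + n_y ≤ 20 with no ties and otherwise
the tie- and continuity-corrected normal approximation.

Caveat: all-pairs distance samples share genes, so they are dependent, and
the rank-sum p computed under the independence null is over-dispersed — a
set of 100 genes contributes ~500 same-chromosome pairs but far fewer
independent observations. Comparisons between strongly clustered and
background sets are unaffected in practice (the planted-clustering p is
astronomically small), but borderline p-values from all-pairs comparisons
should be read qualitatively. The calibration suite therefore demonstrates
uniformity of the null p on distances from disjoint gene pairs, where
independence actually holds.

## Co-expression network

Input is the residual of the rlog matrix on covariates + SVs (per-gene OLS;
rank-deficient designs are rejected naming the collinear columns). Pearson
correlation is used throughout (not biweight midcorrelation), recorded in
the result metadata.

Soft threshold: for each candidate power the signed adjacency
((1 + cor)/2)^β is built, connectivity k summed, k binned into 10
equal-width bins, and log10(bin frequency) regressed on log10(bin mean k);
the signed fit index is −sign(slope)·R². β is the smallest power with index
≥ 0.85. When no power qualifies, the index is uninformative — raising the
power always sparsifies the network toward an apparently better fit, so an
argmax rule drifts to the largest candidate and dissolves weak modules —
and the conventional signed-network default for the sample size is used
instead (18 / 16 / 14 / 12 for n < 20 / 30 / 40 / ≥ 40), with a warning.

TOM is computed densely as (A² + A) / (min-k + 1 − A) with unit diagonal.
Module detection is average-linkage clustering of 1 − TOM with a
deterministic height-scan cut: candidate heights are the
{0.05, 0.06, …, 0.99, 0.995} quantiles of the dendrogram merge heights (the
grid reaches low quantiles because with many unstructured genes most merges
concentrate in a narrow band near the top of the dendrogram, far above the
heights at which real modules are still separate). At each height, clusters
count as modules when they have ≥ minModSize (default 40) members *and* are
cohesive — mean intra-cluster dissimilarity at most 0.9× the global mean —
which prevents arbitrary chunks of an unstructured dendrogram from
qualifying. The chosen height maximises (module count, genes covered by
modules), remaining ties resolved toward the smallest height. This is a
deterministic, oracle-testable replacement for dynamic hybrid tree cutting
that preserves the minimum-module-size semantics; on planted five-module
cohorts it recovers the truth with ARI > 0.97.

Eigengenes are the first right singular vector of the standardised module
submatrix, unit variance, sign-anchored so the mean correlation with member
genes is positive (making all results invariant to global sign flips).
Modules merge when their eigengene dissimilarity (1 − cor, average linkage)
falls below mergeCutHeight = 0.15, iterated to a fixed point; genes with
kME < 0.7 are returned to the background and modules falling below the
minimum size dissolve. Module–trait association is the Pearson correlation
of each eigengene with status, p from the t transform on n − 2 df. GS/MM
follow the standard definitions; per trait-associated module the
correlation of |GS| with own-module MM is reported with its t-test p.

Hubs: within a module, the top-500 largest-weight edges are kept (ties by
lexicographic gene-id pair), degree is the count of incident kept edges, and
the top ⌈5%⌉ of genes by degree are hubs (degree ties by incident weight,
then id). The top-edge subgraph exports to GraphML.

## Marker enrichment

The specificity index of gene g in type t is the mean rank of g (descending
fold change) over the pairwise comparisons of t with every other type,
computed on log expression; non-positive inputs are shifted with a warning.
The permutation null shuffles each gene's values across types independently;
within each type the null SI values are pooled across genes, and the pSI
p-value is the plus-one-smoothed fraction of pooled null SIs ≤ observed.
Pooling puts the attainable floor at 1/(1 + n_perm·G) — a per-gene-only null
cannot drop below ~1/T for even a perfectly specific gene, because its own
shuffles land it back in its type with probability 1/T — and keeps p uniform
under exchangeability. Marker sets at thresholds 0.01 / 0.001 / 0.0001 are
nested by construction; 0.05 is excluded by default for its false-positive
rate. Enrichment is a one-sided (greater) Fisher exact test on the in-module
× in-set table over the universe of genes present in both the network input
and the marker resource (recorded in metadata), Bonferroni-corrected across
the module × set grid within each threshold.

## GWAS set enrichment

SNPs (whitespace-delimited summary statistics; SNP/CHR/POS-or-BP/P header
aliases accepted, duplicate SNP ids keep the smallest p) are assigned to all
genes whose strand-aware window contains them: [start − 20 kb, end + 10 kb]
on +, [start − 10 kb, end + 20 kb] on −, inclusive on 1-based positions.
Gene score = −log10 of the best assigned SNP p; genes with no SNP are
omitted rather than scored 0; the ranking sorts by descending score with
id tie-breaks, over all scored genes by default.

The enrichment score walks the ranking, incrementing by |score|^w
(normalised over the set, w = 1 by default; w = 0 gives the classic KS
statistic and is invariant to monotone score transforms) at hits and
decrementing by 1/(N − m) at misses; ES is the signed maximum deviation,
positive preferred on exact magnitude ties. The null draws `n_perm` (default
20,000) uniformly random same-size gene subsets — equivalent to permuting
gene labels — and is computed vectorised by evaluating the running sum only
at hit positions, where its extrema occur. Reported per set: z-scaled ES
(size-corrected, comparable across sets), plus-one-smoothed one-sided
empirical p (primary; the z-score is descriptive), BH FDR across sets, and a
significance flag at FDR < 0.05. Sets with fewer than 10 mapped genes are
skipped. A negative-control GWAS (e.g. height) runs through the identical
path and is reported side by side; nulls are cached per set size within one
call. Marker-restricted sub-modules of trait-associated modules are tested
alongside full modules in the pipeline. LD-aware scoring is out of scope —
near-uniform SNP coverage is assumed, as in the synthetic generator.

## Synthetic data: what it emulates, and what it does not

Counts follow log μ = baseline + status·lfc·ln2 + batch·b + Σ λ f + log L
with NB sampling at gene-wise log-normal dispersions (α median 0.2), baseline
~ lognormal(log 200, 1), library factors lognormal(0, 0.15). Defaults: 2,000
genes, 30 cases / 60 controls, five modules of 100 genes with loadings
U(0.8, 1.2) on N(0,1) factors, 10% DE genes at |log2FC| = 1 concentrated
with a coherent sign in module 1 (so the module is trait-associated and
carries the GWAS signal-gene set), an optional two-level batch on 30% of
genes, and case/control covariate imbalance (age +1 SD, BMI +0.5 SD, mild
sex/race skew) injected pre-matching so the matching stage has real work.
Annotation places genes non-overlapping with exponential spacing (mean
200 kb) over 10 chromosomes; with clustering on, DE genes pack at 100×
tighter spacing. GWAS p-values are Uniform(0,1) except in signal-gene
windows, where they draw Beta(1/(1+strength), 1); marker sets share exactly
round(overlap·size) genes with the target module. Everything is
bit-reproducible from (config, seed), and the pipeline derives each stage's
seed deterministically from the master seed.

What passing on this generator shows: the statistics are implemented
correctly (exact oracles), calibrated under their nulls, and able to recover
planted structure at realistic desk-scale sizes. What it does not show:
robustness to GC/length biases, LD structure, correlated covariates,
non-Gaussian latent factors, outlying samples, or count distributions beyond
NB2 — none of which the generator emulates. Problem sizes in the test suite
and acceptance script (2,000 genes, n = 90, 10 recovery seeds, 20 FDR
replicates, 200 calibration replicates at 1,000 permutations, demo
permutations 5,000) were chosen as the smallest at which the measured
quantities are stable; the statistical procedures themselves are
size-agnostic.

## Known limitations

- Surrogate variables absorb unprotected latent biology, attenuating some
  co-expression modules (see above); choosing n_sv against the expected
  latent dimension is the user's responsibility.
- The independent-filter argmax is mildly liberal under a global null.
- All-pairs distance comparisons carry dependent observations; their
  Wilcoxon p-values are qualitative.
- The rlog here is a shifted log, not a shrinkage transform; at very low
  counts it is noisier than the transform used by the reference DE tool.
- Fisher marker enrichment treats genes as exchangeable; no correction for
  gene length, expression level or co-expression within sets.
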