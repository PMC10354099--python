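# Methods

This note documents the statistical models implemented in `tmescreen`, the
choices made where the design was genuinely open, what the synthetic-data
generators do and do not emulate, and the package's known limitations. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Enrichment engine

**ssGSEA.** A sample's genes are ranked by expression, descending, with ties
broken lexicographically by gene id so that every score is deterministic.
Ranking scores are the within-sample ranks (top gene G, bottom gene 1)
rather than raw values: the pipeline pools microarray and RNA-seq inputs,
and rank normalization makes the score insensitive to their different
marginals. The enrichment score is the sum over all ranked positions of the
difference between the cumulative |rank|^α-weighted in-set fraction and the
cumulative uniform out-of-set fraction. α defaults to 0.25 (the original
single-sample formulation); 0.75 is selectable. At α = 0 the score reduces
to an unweighted cumulative-difference statistic with a simple enumeration
oracle, which the tests exploit. An optional min–max normalization rescales
each set's scores by their cross-sample range; both raw and normalized
outputs are exposed because correlation analyses may use either.

**Two-class GSEA.** Genes are ranked by signal-to-noise,
(μ₁ − μ₀)/(σ₁ + σ₀), each σ floored at 0.2·|μ| (0.2 when μ = 0) in the
desktop-tool convention — the floor keeps the metric defined for
single-replicate classes, which matters because paired sphere/adherent
designs often have one sample per phenotype. The ES is the
maximum-magnitude deviation of the weighted KS running sum (weights
|metric|^p, p = 1 by default; sets whose in-set weights are all zero fall
back to uniform steps). Significance uses gene-set permutation by default
(random same-size sets; phenotype permutation is available but falls back
with a warning below 3 samples per class). The nominal p is the
`(k + 1)/(n + 1)` estimator over same-signed permutation ES values, so p is
never zero; NES divides the ES by the mean |same-signed permutation ES|;
the FDR q pools normalized permutation scores across sets in the usual
GSEA fashion. All permutations are seeded and reproducible.

**Over-representation and FDR.** Hypergeometric upper-tail p via
`scipy.stats.hypergeom`; Benjamini–Hochberg step-up q-values via
`statsmodels` (the step-up contract is verified against an independent
implementation in the tests). The over-representation universe is the set
of genes present in the expression matrix, not all annotated genes —
enrichment against an inflated universe would be anti-conservative.

## Two-arm screen

Arm A stratifies tumors by a stemness score — signature ssGSEA by default,
or an externally supplied per-sample index passed through unchanged — into
top/bottom quartiles (the threshold is configurable; no canonical value
exists). "Highly expressed in stemness-high tumors" means a two-sided
Wilcoxon rank-sum p ≤ 0.01 plus a log2 fold-change floor of 0.585 (1.5×);
a rank-based test was chosen for robustness across platforms. TF target
sets are then tested for over-representation among those genes at
P < 0.01 and FDR q < 0.05.

Arm B runs gene-set-permutation GSEA of every TF target set on each
sphere-vs-adherent contrast and calls a factor functional when its targets
are positively enriched (nominal P ≤ 0.05, NES > 0) in at least
`min_datasets` datasets, defaulting to ⌈0.3 × n_datasets⌉ — a recurrence
floor mirroring "enriched in a substantial minority of cancer types"
convergence logic. Recurrence filtering is applied to arm B only; arm A
operates on a single pooled cohort and has no recurrence notion (a
configurable recurrence option is deliberately left off by default).

The screen report is the intersection of the two arms with both arms'
statistics attached; it is order-independent and idempotent.

## Marker-set deconvolution and correlation landscapes

Microenvironmental signals (neural infiltration, CRE activity, stemness)
are scored per tumor as the ssGSEA score of the corresponding marker set —
no regression- or reference-profile-based deconvolution is attempted, since
marker-set scoring is the method under study. Pairwise Pearson r with the
two-sided t-transform p is computed on pairwise-complete observations;
constant columns are reported missing with a warning. Cohort fractions
count cohorts with sign(r) matching the requested direction and p ≤ 0.05
(the qualification rule is configurable; sources reporting "k/n cohorts"
rarely state one).

The repository ships no real neuron marker lists; marker sets are user
input (GMT), and fixtures use synthetic sets.

## Prognosis

Per-gene survival association is the Cox proportional-hazards **score test
at β = 0** with Breslow handling of ties: z = U/√V where U sums
(xᵢ − mean of x over the risk set) over events and V sums the risk-set
variances. The score test needs no iterative fitting, cannot diverge on
monotone likelihoods, and for a binary covariate is exactly the two-group
log-rank z — a property the tests verify against both a pure-Python
risk-set enumeration and `lifelines` (on tie-free data; with ties lifelines
applies the hypergeometric multiplicity correction that the Breslow score
test omits). Positive z means higher expression, worse outcome. Zero events
make z undefined (reported missing); constant covariates give z = 0.

Signature prognosis uses the unweighted Stouffer combination
meta-z = (Σ Zᵢ)/√N over the N signature genes present in the z table
(absent genes are dropped and logged, N adjusts). The panel function
computes meta-z per cohort × signature and compares two signatures with a
two-sided paired t test across cohorts.

The optimized-cutoff KM split scans candidate cutoffs (default: expression
percentiles 10–90 in steps of 5) and returns the minimal log-rank p. Since
minimal-p selection inflates type-I error, an Altman-style corrected p
(−1.63·p·(1 + 2.35·ln p) for the inner 10–90% selection window, clipped to
[p, 1], set to 1 when p ≥ 0.1 where the approximation fails) is always
reported alongside.

## Limiting dilution

The single-hit Poisson model: a well seeded with d cells responds with
probability 1 − exp(−λd), λ = active cells per cell, displayed as "1/x"
with x = 1/λ. The log-likelihood is maximized by safeguarded Newton
iteration on log λ with geometric bisection fallback, score tolerance
1e-10, bracketed in [1e-12, 1] (λ cannot exceed one active cell per cell).
Wald CIs come from the observed information on log λ; when the estimate
sits on a boundary (no responding wells, or every well responding) the
function returns one-sided likelihood-based intervals (log-likelihood drop
χ²₀.₉₅,₁/2) with explicit `boundary` flags. A Pearson χ² of observed vs
fitted per-dose responses (df = doses − 1) is attached as a single-hit
goodness-of-fit check; no multi-hit or heterogeneity model is fitted.

Group comparison is the likelihood-ratio test
χ² = 2(Σ per-group max log-lik − pooled max log-lik), df = groups − 1.
The implementation was cross-checked against a binomial GLM with
complementary log-log link and log-dose offset (identical MLE) and an
unconstrained-likelihood LRT oracle (p-values agree to 1e-15).

Dose ladders follow standard practice: (100, 50, 25, 12, 6, 3, 1)
cells/well in vitro and (50000, 10000, 1000, 100) cells/injection in vivo.
A caveat the calibration tests make visible: on the in vivo ladder the top
doses saturate near response probability 1, so nearly all information about
frequencies of order 1/100–1/300 comes from the lowest dose, and two-group
power is correspondingly modest (≈0.8 for 1/300 vs 1/60 with 10 animals
per dose).

## Single-cell scoring

Counts are log1p-transformed and ranked within each cell; dropout zeros tie
at the bottom and are broken lexicographically, keeping scores
deterministic. Gating labels a cell CSC iff every positive marker count
exceeds the threshold (default 0) and every negative marker does not;
quantile-based thresholds are configurable. Group comparison is Welch's
two-sample t test. No clustering, embedding, doublet removal or other QC is
performed — inputs are assumed pre-filtered.

## Synthetic data generators

All generators are pure functions of (spec, seed) using a single
`numpy.random.default_rng` stream; identical seeds give bit-identical
output.

*Bulk cohorts*: latent factors drawn from a user-supplied correlation
matrix (validated symmetric PSD); each planted program adds
amplitude × factor (or a flat shift in a random carrier fraction) to its
genes on top of a gene-specific baseline (mean 7, SD 1 across genes) and
i.i.d. Gaussian noise (SD 1) on the log scale. The noise model is Gaussian
because every downstream statistic is rank-based or location-based; the
exact marginal is immaterial. Survival times are exponential with
log-hazard linear in designated factors; censoring marks a configurable
fraction of subjects (default 30%) as observed for a uniform fraction of
their event time, which hits the requested censoring rate exactly in
expectation.

*Sphere/adherent pairs*: one sphere and one adherent profile per dataset by
default (matching typical paired designs, hence the gene-set permutation
default in GSEA); planted TFs up-shift their targets by 1.5 noise-SD in the
sphere samples of their active datasets.

*Screen scenario*: 1500 genes, 120 tumors, 50 TFs with 40 targets each, 5
planted TFs whose (disjoint) target blocks load on the stemness factor at
0.8 SD, a 50-gene stemness signature at 1.0 SD, and 17 paired datasets with
each planted TF active in 10.

*Compendium*: 32 cohorts × 300 tumors × 2000 genes; 30-gene marker sets
loading at 2 SD — the specificity expected of curated cell-type markers,
and large enough that the ssGSEA score is nearly linear in the latent
factor. A smaller universe or weaker markers attenuates the recovered
correlation: with three correlated 30-gene programs in an 800-gene
universe, cross-set rank interference alone pulls a planted ρ = 0.5 down
to ≈0.42.

*Single cells*: negative-binomial counts (dispersion 0.5), log-normal
library sizes (σ = 0.3), gene base abundances log-normal. CSC cells
(default 20%) shift the stemness program by 1.0 log-unit and share a
per-cell latent intensity u ~ N(0,1) multiplying both pluripotency and
mitochondrial means by exp(coupling·u), coupling 0.7 — this is what creates
the correlated program scores the scoring stage must recover. Two marker
genes are high in CSCs (mean 6) and near-silent otherwise (mean 0.05).

What the generators do **not** emulate: batch and platform effects, real
gene-gene correlation structure, realistic library-size confounding with
cell state, dropout that depends on expression, or real marker catalogs.
Passing tests therefore demonstrate that the statistics recover the
structures they target under their stated models — not performance on any
particular public dataset.

## Orchestration and determinism

`run_all` executes simulate → screen → deconvolve → prognosis on a single
config, with every stage seeded from the config seed. Outputs use fixed
float formatting (6 significant digits in TSVs) and sorted JSON keys, and
the provenance record deliberately contains no wall-clock time, so reruns
with the same config are byte-identical. Runs are cached on a content hash
of the config (excluding the output path); `force` bypasses the cache.

## Problem sizes

Test and acceptance runs use the generator defaults above (the compendium
at n = 300 per cohort, screens over 10–20 seeds, 500-simulation dilution
calibrations), chosen as the smallest sizes at which the planted effects
are comfortably identifiable; everything completes in well under a minute
apiece on one CPU.

## Known limitations

* The stemness scorer is a signature-ssGSEA stand-in with an external-score
  pass-through; the machine-learning stemness index used in some sources is
  not retrained here.
* Multivariate Cox models with clinical covariates are out of scope; the
  prognosis module is deliberately univariate plus meta-combination.
* GSEA leading-edge reporting and plotting are not implemented.
* The Altman cutoff correction is an approximation valid for small minimal
  p on the inner 80% selection window; outside it the corrected p is
  conservatively set to 1.
* Gene identifiers are opaque case-sensitive strings: no aliasing, probe
  mapping or ortholog handling anywhere.
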