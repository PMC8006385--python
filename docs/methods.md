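# Methods

This note documents the statistical models, numerical choices, and known
limitations of otukit, in the spirit of the methods documentation shipped by
statistical toolkits.

## Data model

A `MicrobiomeExperiment` is a validated triple (counts, taxonomy, sample
metadata). Counts are non-negative integers; float inputs integral to within
1e-9 (e.g. `5.0` from exporters) are cast, anything else is rejected with the
offending label. Feature identity is the row-label string. Taxonomy is
optional; its absence disables only level aggregation. Missing taxonomy
entries use the explicit marker `unclassified` — never the empty string — so
aggregation at a rank collects unassigned features into one explicit bucket.

Metadata columns are typed by a deterministic rule: *continuous* iff numeric
with more than 8 distinct values, else *categorical*. The cutoff is arbitrary
but fixed; it exists so that downstream choices (test menus, binning,
plot-table shapes) never depend on floating heuristics.

Empty selections in `pick_samples` / `pick_features` are errors rather than
empty objects: every downstream statistic is undefined on zero samples or
features, and failing at the subsetting step gives a better diagnostic.

## Transforms and filtering

* relative abundance: per-sample proportions; columns sum to 1 within 1e-12.
* logCPM: `log2(CPM + 1)`. The +1 pseudocount maps zeros to exactly 0 and
  makes the transform scale-invariant in the library size. Other conventions
  (e.g. `log2(CPM + 0.5)`) shift zeros off the origin; the +1 form was chosen
  for its exact-zero property and is used consistently by the moderated-t
  path and the biomarker module.
* aggregation (`upsample_counts`) sums integer counts grouped by the label at
  the target rank, so per-sample totals are conserved exactly; lineage columns
  above the target rank are retained when unambiguous within a group and set
  to `unclassified` otherwise.

Feature filtering is a conjunction: mean raw count ≥ t₁ AND mean relative
abundance ≥ t₂ AND prevalence ≥ t₃, minus an explicit discard list. The
pipeline order is fixed — sample filters first, then feature criteria
evaluated on the retained samples — because prevalence and mean relative
abundance depend on the sample set; with any other order the result would
depend on call sequence. Filtering is idempotent: removing features can only
raise the survivors' relative abundances, and mean counts and prevalence are
unaffected by removal of other features.

Covariate discretization defaults to quantile (equal-count) bins, which are
robust to skewed clinical covariates; equal-width bins are available by flag
and explicit breakpoints are honoured verbatim. Bins are `[lo, hi)` with the
final bin closed.

## Diversity and distance statistics

Alpha metrics are computed on per-sample proportions after optional rank
aggregation. The Wilcoxon rank-sum test switches to exact enumeration when
both groups have ≤ 8 tie-free observations, and otherwise uses the
tie-corrected normal approximation with continuity correction; the Welch
unequal-variance t and the tie-corrected Kruskal-Wallis H are delegated to
scipy.

Bray-Curtis is computed on relative abundance by default: with raw counts the
index is dominated by library-size differences, which are technical rather
than biological. A raw-count option is retained. Jaccard is the binary
presence/absence form on raw counts (abundance-weighted variants exist but
are a different statistic). Bray-Curtis does not satisfy the triangle
inequality in general; no metric axioms beyond symmetry, zero diagonal, and
the [0,1] range are asserted.

PERMANOVA uses the squared-distance decomposition (see README) with a
label-permutation null. The p-value estimator is `(1+b)/(1+m)`, which never
returns 0 and is the standard finite-sample-valid permutation estimate.
Singleton groups are allowed with a warning (their within-group term is 0),
matching common field practice; fewer than 99 permutations triggers a
resolution warning. Empirical type-I error at α = 0.05 on exchangeable
two-cluster nulls (n = 10+10, 199 permutations) is verified by simulation in
the acceptance suite.

Distance-based Wilcoxon/Kruskal-Wallis tests compare pooled within-group
against between-group pair distances. Pair distances are not independent
observations, so these p-values are descriptive rather than exact; PERMANOVA
is the calibrated test and is the default.

## Ordination

PCA centers features but does not scale by default: abundance variances are
meaningful, and unit-scaling would inflate rare noisy taxa (a scaling flag is
provided). Axes are oriented so the largest-magnitude loading is positive,
making signs reproducible across LAPACK implementations. PCoA drops negative
eigenvalues (no Cailliez/Lingoes correction) and reports their count and
total magnitude as a diagnostic; explained variance is relative to the sum of
positive eigenvalues. On Euclidean-embeddable distances PCoA reproduces PCA
scores up to per-axis sign (verified to 1e-8 in the acceptance suite). t-SNE
and UMAP are delegated backends with a determinism contract only (same seed,
same input → identical output); when a backend is missing a typed capability
error is raised and the rest of the toolkit is unaffected.

## Differential abundance

**Size factors** are the zero-tolerant median-of-ratios: per-feature
geometric means over strictly positive counts, per-sample median ratio over
features positive in that sample, rescaled to geometric mean 1. The
zero-tolerant variant keeps sparse microbiome features usable (the classic
all-positive-features variant can run out of reference features entirely).

**NB-Wald path.** Per feature, a negative-binomial GLM with log link,
`Var = μ + αμ²`, and `log s_j` offsets. Coefficients are fit by IRLS;
dispersion by bounded maximum likelihood on [1e-8, 10], alternated with the
coefficient fit from a method-of-moments start. The dispersion objective uses
the Cox-Reid adjustment `+½ log det(XᵀWX)`: the plain profile MLE is biased
low because it ignores the degrees of freedom consumed by the fitted mean,
which makes Wald tests anticonservative (observed null type-I ≈ 0.10 at
α = 0.05 without the adjustment, ≈ 0.06–0.09 with it). Wald SEs come from the
observed Fisher information; non-converged features are flagged, excluded
from the BH denominator, and reported with missing p. There is no shrinkage
of dispersions toward a trend, so this path is DESeq2-*style*, not
DESeq2-equivalent; agreement with pyDESeq2 in ranking (Spearman ρ of p-values
≥ 0.9) and effect sizes (r ≥ 0.95) is verified in the test suite.

**Moderated-t path.** OLS of logCPM on the design, empirical-Bayes
moderation of residual variances with a scaled-inverse-chi-square prior.
Hyperparameters are moment-matched on `log s_g²` using digamma/trigamma
identities, with the trigamma inverse solved by Newton iteration; when the
observed spread of log-variances does not exceed pure chi-square sampling
noise the prior df is infinite and variances are pooled (with a warning in
the fallback case). Since logCPM is base-2, the group coefficient is the
log2 fold change directly. The d₀ → 0 and d₀ → ∞ limits (ordinary t; pooled
variance) are exposed for diagnostics and verified as exact reductions.

**Extended columns.** "Percentage" is interpreted as the group mean relative
abundance (the plausible alternative — percent of total reads — differs only
by a constant per group and is not separately reported). Prevalence is the
group fraction of samples with nonzero count. The group-size-adjusted fold
change is `(pct₁ + ε)/(pct₂ + ε)` with ε = 1e-6: interpretable, finite even
when a feature is absent from one group, and monotone in the raw ratio.

BH is the only multiple-testing procedure offered (the field default for
"adjusted p"). Targets are restricted to two-level factors; multi-level
phenotypes must be recoded to pairwise contrasts.

**Known limitation (verified, not fixable by estimation).** When a fraction
of taxa shifts in one direction without compositional renormalization — as
in the synthetic generator's design, which keeps true log2FC interpretable —
every median-of-ratios normalization absorbs part of the shift (~±5% per
group at 10% DA taxa and log2FC 2). Null taxa then acquire a small
systematic log2FC (≈ −0.17 under those conditions), which BH at 0.05 turns
into excess weak discoveries: empirical FDR ≈ 0.2–0.3 instead of the nominal
0.05–0.10. pyDESeq2 shows the same FDR on identical data, confirming this is
a property of the normalization under one-sided compositional change, not an
implementation defect. Sensitivity and effect-size recovery are unaffected.

## Biomarker discovery

Candidacy is sparsity-based: nonzero L1-logistic coefficients, or positive
forest impurity importances (optionally truncated to the top
`candidate_fraction` of features). The importance score — the fraction of the
N·K training folds whose candidate set contains the feature — is only
meaningful if candidate sets are genuinely sparse, which the L1 penalty and
the truncation option provide. Hyperparameters are tuned per fold by an inner
3-fold grid search (8 log-spaced inverse-penalty points 1e-3…1e3 for
logistic; features-per-split ∈ {√p, p/3, p/5} for forests).

The evaluation stage uses a *fresh* repeated CV (seed-offset stream) on the
fixed selected panel, refitting hyperparameters per training fold and scoring
only held-out samples, so no held-out sample ever influences the features or
the model evaluated on it. Selection is not repeated inside evaluation: the
reported AUC measures the chosen panel, not the selection procedure, and is
therefore mildly optimistic about the full pipeline — the classic caveat of
evaluating a fixed signature. Mean ROC is the vertical average of per-fold
curves on a fixed 101-point FPR grid; mean AUC is the mean of per-fold
trapezoidal AUCs. A threshold of P = 0 selects every feature seen in any
fold (strictly positive score). Datasets under 30 samples trigger an
overfitting warning.

## Synthetic data generator

`simulate_experiment` draws a Dirichlet baseline composition (concentration
0.5 by default — a skewed, microbiome-like rank-abundance curve), designates
`round(prop_da · n_taxa)` taxa uniformly at random, multiplies their group-2
means by `2^log2fc`, and samples NB counts with `Var = μ + αμ²` around
log-normal library sizes (default mean 1e5, CV 0.3 — typical of amplicon
experiments after QC). The NB parameterization matches the inference model so
parameter recovery is well-posed. The effect is applied without renormalizing
non-DA taxa: true log2FCs stay interpretable, at the cost of the
compositional leakage documented above. Metadata carries the group factor and
a continuous nuisance covariate; taxonomy assigns species to random genera
and phyla (default 20 genera in 4 phyla). All randomness flows from the
single seed.

`simulate_two_cluster_profiles` blends two independent Dirichlet baselines by
a divergence parameter in [0,1]; divergence 0 yields exchangeable groups (the
PERMANOVA null construction), large divergence yields well-separated
community clusters.

What the generator does *not* emulate: sequencing error and chimeras,
zero-inflation beyond NB sparsity, taxon-taxon correlation structure,
phylogenetic signal, or batch effects. Passing tests therefore demonstrate
statistical correctness under the stated generative model, not robustness to
every real-data pathology.

## Problem sizes used in the automated checks

The acceptance checks use 500–1000 PERMANOVA null replicates at n = 10+10
with 199 permutations, 10 simulation seeds at n = 20+20 × 200 taxa for the
NB path, 500 features for the moderated-t null, 10 permuted-label seeds at
n = 25+25 × 50 taxa for the biomarker null, and 20–50 random experiments for
round-trip checks — sizes chosen to give stable Monte-Carlo estimates on a
single CPU in a few minutes.

## Interfaces

The CLI mirrors the analysis workflow as subcommands (import, summarize,
filter, abundance, diversity, dimred, diffabund, biomarker, simulate), each
writing TSV/JSON outputs plus a run-log (parameters, seed, version, input
SHA-256 digests) for replayability. Visualization is emitted as plot-ready
long-format tables; static image rendering was deliberately left out — the
tables load directly into any plotting layer. Group-aggregated abundance
sums counts within groups *before* computing relative abundance, so the
group bar is the community profile of the pooled group, not a mean of
per-sample proportions.
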