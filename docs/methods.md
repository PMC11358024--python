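# Methods

This note records the models, parameter choices and numerical decisions
behind `transdep`, and what the synthetic-data tests do and do not
demonstrate about real cohorts.

## Essentiality models

Per-gene elastic nets use mixing α = 0.5 (equal L1/L2 weight) on features
standardized within each training fold; the penalty path has 100 log-spaced
values spanning four decades below λ_max = max|Xᵀ(y−ȳ)|/(n·α), and λ is the
minimizer of the mean 10-fold CV error. "Cross-validation R" is the Pearson
correlation between *pooled* out-of-fold predictions and the observed
scores (pooled rather than fold-averaged for stability at n ≈ 100; the
choice matters little but is fixed here). Its P value is the conventional
two-sided t approximation with n − 2 df, BH-adjusted across all attempted
genes; the pass rule is R > 0.2 and FDR < 10⁻³. Genes are attempted only
when at least five lines fall strictly below the −0.5 dependency cutoff and
five at or above it. The target gene's own expression is allowed as a
feature (self-inclusion is reported as `self_rank`). Coefficients are
stored on the standardized scale together with the full-data feature
means/SDs, so a serialized model is self-contained. Multi-omics models
concatenate expression with binary mutation and copy-number features after
per-feature standardization; confounder-null models use lineage one-hot
plus simulated continuous nuisance covariates and serve as an empirical
floor. Mutation classifiers are logistic elastic nets (CV AUC reported),
attempted only at prevalence within (2%, 98%).

## Alignment

Quantile normalization maps every column onto the mean-of-sorted reference
of all pooled samples (average ties). Contrastive PCA eigendecomposes
C_fg − α_c·C_bg with the *target* cohort as foreground — the variance to
remove is the target-specific stromal signal — and contrast weight
α_c = 1.0 by default (the weight is not dictated by the procedure; 1.0
treats both cohorts symmetrically and is configurable). The top k
components (4 tumor / 3 PDX / 0 healthy) are removed from both cohorts by
an orthogonal projection in per-gene-centered space; removal from both
sides is the default because both representations should live in the
common subspace (a flag restricts removal to the target). Cluster-matched
correction runs joint k-means (fixed seed; k defaults to the number of
lineages) and subtracts, per target cluster, the offset to the nearest
cell-side centroid. Healthy cohorts are corrected by quantile normalization
plus a per-gene location–scale adjustment to the cell cohort's means/SDs,
shrunk toward the global adjustment with weight n/(n + n₀), n₀ = 10 — a
deliberate, documented stand-in for empirical-Bayes batch correction that
behaves identically for the location/scale components at these cohort
sizes. Gene-set mismatches are resolved by intersection (input order
preserved), never by imputation.

## Transposition

Only passing models are transposed; a model with any feature missing from
the target is skipped and logged rather than zero-filled (zero-filling
silently pulls scores toward the intercept). Predictions are rescaled per
gene by least squares of measured on predicted scores in the cell cohort;
the map is affine and monotone, so per-gene correlations and sample
rankings are unchanged (asserted exactly in tests). Lineage structure is
summarized by Ward-linkage clustering on Euclidean distances with the
adjusted Rand index against known labels; gain-of-function association uses
the two-sided Wilcoxon rank-sum test with a directional flag when the
carrier median score is more negative.

## NormLRT

The selective-dependency statistic is 2·(ℓ̂_skew-t − ℓ̂_normal), clamped at
zero. The skew-t is the Azzalini location–scale family
f(x) = (2/ω)·t_ν(z)·T_{ν+1}(αz√((ν+1)/(ν+z²))), z = (x−ξ)/ω, which
contains the symmetric t at α = 0 and approaches the normal as ν → ∞; ν is
bounded to [2.1, 100] (finite variance below, "normal-like" above).
Maximization uses L-BFGS-B from three starts (symmetric, left-skew,
right-skew); negative raw LRT values are optimizer noise (the nesting is a
limit) and are clamped and logged. No null P values are attached — the
statistic is used for ranking only. Cross-cohort comparability uses a
bootstrap: columns are resampled with replacement to the target size, the
statistic recomputed (50 draws by default) and the slope of source on mean
resampled score fitted through the origin, because a statistic of zero must
map to zero; the statistic grows roughly linearly with n, so the slope
tracks the cohort-size ratio.

## Synthetic lethality

Lasso (5-fold CV, minimum-error λ) regresses each gene's dependency
profile on the binary LOF matrix restricted to 3–70% prevalence.
Candidates need a coefficient below −0.3 — negative because carriers must
be *more* essential — measured on the original 0/1 predictor scale: binary
predictors share one scale, reference implementations report original-scale
coefficients, and a standardized threshold of 0.3 would demand
unrealistically large effects at low prevalence (a −0.6 carrier shift at
20% prevalence has a standardized coefficient of ~0.24). Confirmation is a
Welch t-test (unequal variances are the safe default) with BH across all
tested pairs at FDR < 0.01. Mutual exclusivity maximizes
score(S) = Σ_s w_s·(2 − k_s) over covered samples (k_s = covering genes in
S; each extra cover subtracts the sample's weight), with weights = negated
essentiality. The search is a multi-start greedy — grown from every seed
gene, keeping the best prefix — which is exhaustive for sets of ≤ 2 and a
strictly stronger heuristic beyond; P values permute weights with the +1
correction (never zero) at 100 permutations, threshold P < 0.01. The
paralog stage keeps annotated paralogs OR pairs with phylogenetic distance
strictly below 1.5.

## Screens

Constructs carry four guides; reads are matched *exactly* on the
concatenated array between the two flanks, everything else tallied
unmapped. TMM factors use the standard doubly-trimmed (30% on M, 5% on A),
inverse-asymptotic-variance-weighted mean of M values against a reference
sample (the one with the most typical upper-quartile proportion), then
normalize to geometric mean 1. L2FCs compare pseudo-counted (0.5)
proportions of each day-14 replicate with the plasmid on TMM-effective
library sizes; replicates are aggregated as mean + one-sample t rather
than a moderated linear model — a deliberate simplification that is
near-equivalent at three replicates. GI scoring z-scores all construct
L2FCs against the NT×NT null, collapses multiple single-KOs per gene to
the median, takes expected = z_A + z_B, and z-scores the
observed-minus-expected differences across DKOs; |diff_z| > 2 calls
synthetic lethality (negative) or buffering (positive).

## Survival and outcomes

The log-rank test is implemented with its O−E decomposition (hypergeometric
accumulation over distinct event times). Maxstat scans unique score values
whose split keeps both groups within the (10%, 90%) quantile band, takes
the cutpoint maximizing |standardized log-rank|, and computes significance
by permuting scores against (time, event) and comparing *maximum* statistics
— exact selection correction at desk scale, no tabulated approximation
constants (200 permutations by default). Cox models come from lifelines
(Efron ties, optional strata); the β = 0 score test is computed directly
(it equals the log-rank test for a binary covariate, asserted numerically).
The outcome scan feeds the permutation-corrected maxstat P into BH at
FDR 0.2 and fits HRs for discovered genes (high dependency = scores at or
below the cutpoint; HR > 1 means worse outcome with higher dependency).
Note the granularity floor: with m permutations the smallest attainable P
is 1/(m+1), so BH can only reject when 1/(m+1) clears q/n_genes. The
predicted-SL carrier group is LOF of the partner AND dependency below the
25% quantile (the quantile is a package decision, echoed in logs). Response
association uses Wilcoxon + ROC-AUC (sensitive = lower score; −0.5 is the
sensitivity cutoff convention) for binary response and Pearson for
continuous burden change, refusing groups under 20. Subtyping selects the
top-100 genes by variance (variance, not MAD — the choice is configurable)
and scores LDA with leave-one-out CV as per-class one-vs-rest AUC, skipping
classes under 5 samples. Driver enrichment takes the lowest 10% of samples
by a gene's score and applies one-sided Fisher tests per variant above its
class prevalence floor (5% mutations, 10% deletions/amplifications), BH
within class.

## Tolerability

Welch t per gene per tumor-type↔healthy-tissue pairing, sign convention
t < 0 = stronger dependency in tumor, BH within pairing. Both maps must be
`predicted+rescaled` from the same model set (checked via a fingerprint) —
comparing scores of different provenance is refused. Toxicity profiling
reports per-tissue set means with a Wilcoxon contrast against the rest of
the genome.

## Synthetic-data generator

The generator defines the study conditions. Expression is log2-scale
Normal(gene mean + lineage shift, 1) with gene means U(4, 10) and lineage
shifts N(0, 1); 20 of 500 genes (defaults) carry essentiality models with
5 features each, coefficients ±U(0.15, 0.30) and noise SD 0.2, keeping
modeled score profiles CERES-like (SD ≈ 0.7 around −0.5); the rest are
N(−0.5, 0.5) noise. Tumor biopsies mix malignant and stromal signal in
*linear* space weighted by Beta(5, 2) purity and are re-logged — additive
contamination in linear space is exactly the situation contrastive PCA
exists for. Planted effects flow through expression: a pair (A, B, Δ)
shifts the expression of A's model features along the least-norm direction
in LOF-of-B carriers so that A's latent and predicted scores both move by
Δ; defaults are Δ = −0.6 at 10–30% prevalence, mirroring a realistic
synthetic-lethal effect against a 3–30% background LOF rate. Survival
times are exponential with log-hazard linear in the hazard gene's
standardized latent score (coefficient −1: dependency worsens outcome) and
administrative censoring at 24 months tuned to ~40–50% events. Screens
draw negative-binomial counts (dispersion 0.05) around plasmid proportions
scaled by 2^(single effects + interaction); every construct has its own
four unique guides. One global seed is stream-split per generator
(`SeedSequence(seed, spawn_key)`), so cohorts regenerate independently and
bit-identically.

What the generator does *not* emulate: genome-scale gene counts and real
identifiers, count-level expression noise, copy-number segment structure,
subclonal heterogeneity, nonlinear expression–essentiality relationships,
and informative censoring. Passing tests therefore demonstrate that each
stage recovers the structure it targets when that structure is present and
reports nothing when absent — not that real-cohort effect sizes will match.

## Validation design choices

- The planted stromal direction for the alignment check is defined as the
  top eigenvector of the model-implied excess covariance (mixed minus
  malignant), Monte-Carlo-estimated from generator parameters alone: the
  admixture is nonlinear in log space, so no single exact direction exists,
  and this is precisely the object the contrastive step estimates.
- The tolerability ranking check plants a driver-dependent gene (carrier
  shift −1.5 at 40–50% prevalence) and runs on purity-1 tumors and
  distortion-free healthy tissue: it validates the window *ranking* in
  isolation, while alignment quality is validated by its own purity
  diagnostic. With both noise sources active, residual per-gene alignment
  biases of ~±0.3 score units dominate any realistically sized planted
  window at 20 modeled genes — a real limitation of transposed maps that
  the purity diagnostic quantifies but does not remove.
- Null calibrations are asserted with stochastic slack (e.g. type-I ≤ 1.5×
  nominal over 100 simulations; BH any-discovery rate within its q level
  over 20 runs), since tighter bounds would fail on binomial noise alone.
- Problem sizes in tests and the acceptance script (cohorts of 100–500
  samples, 200–500 genes, 20-gene model sets, 10–100 simulation replicates)
  were chosen as the smallest scales at which the planted effects are
  comfortably identifiable; all are parameters, not limits.

## Known limitations

- The location–scale healthy-tissue correction removes cohort-wide
  biological differences along with batch effects (the classic confound);
  tissue-*specific* contrasts within the healthy cohort survive.
- The mutual-exclusivity objective is one member of the family of weighted
  exact-cover scores; its formula is fixed and brute-force-tested, but other
  published variants weight overlaps differently.
- NormLRT values depend on the optimizer reaching the skew-t optimum; with
  three starts non-convergence is rare and flagged, but pathological
  profiles can under-score.
- `pfi_scan` computes HRs only for genes passing the FDR threshold, to keep
  genome-wide scans inside a desk-scale budget.
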