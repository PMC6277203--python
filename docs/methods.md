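# Methods

## Study design addressed

The pipeline targets a two-factor challenge experiment: fish families
selected for cold tolerance (resistant vs sensitive, 3 families each, 7
fish per family per temperature arm) are held at a control temperature
(24 °C) or cooled to 12 °C; gut microbiomes are profiled by 16S counts in
two gut parts (anterior/posterior, 168 samples from 84 fish) and the host
response by a liver expression matrix (one profile per fish). The
scientific questions are (i) how temperature and host tolerance structure
the gut community, (ii) whether the resistant host's microbiome is buffered
against the temperature shift, and (iii) whether microbiome and host
transcriptome responses are linked.

## Statistical procedures

**Rarefaction and α-diversity.** Features observed in fewer than two
samples are discarded; each sample is subsampled without replacement
(multivariate hypergeometric) to a common depth, default 6000 reads, with
shallower samples dropped and reported. Richness is the count of features
with positive counts; Shannon H′ = −Σ p_i log p_i uses log base 2 by
default (base e selectable). Diversity responses are modeled with a
random-intercept linear mixed model (REML, via statsmodels MixedLM):
temperature and tolerance as treatment-coded fixed effects, family as the
random intercept. Each fixed factor gets a joint Wald F on its
coefficients. The fixed-effects covariance is computed directly from the
estimated variance components by the per-group Woodbury identity rather
than from the observed information, because the latter is numerically
unstable when the group variance is estimated at the zero boundary; at that
boundary the test collapses exactly to the ordinary-regression F. The
denominator df convention is explicit and configurable: `residual`
(n − rank X, default) or `between_within` (additionally subtracting the
between-group df); no convention reproduces every historically reported df,
so the report always states which was used.

**β-diversity and distance contrasts.** Bray–Curtis dissimilarity on
(rarefied) counts; Jaccard on presence/absence with a configurable
detection threshold (default: value > 0, the natural choice for normalized
expression where any positive estimate is a detection). Principal
coordinates come from the eigendecomposition of the Gower-centered matrix;
negative eigenvalues (non-Euclidean metrics) are dropped and their total
mass reported, and explained-variance fractions are relative to the
positive-eigenvalue mass. Group contrasts compare two selected sets of
pairwise distances (a pair-selector names a metadata stratum and either
within-level or between-level pairs of a factor) by a two-sample pooled-
variance t statistic with a Monte-Carlo null, default 1000 permutations,
Bonferroni-corrected over the declared comparisons. Two permutation schemes
are provided. The default relabels *sample* identities on the distance
matrix and re-extracts both pair sets; this preserves the positive
correlation between distance pairs that share a sample and is calibrated
(null p-values uniform — verified over 200 null data sets). The classical
alternative (`permute="pairs"`) pools the distances themselves as
exchangeable units; it reproduces the traditional nonparametric distance
t-test but overstates significance for within-group pair sets, because m
samples yield m(m−1)/2 correlated pairs that the pooled null treats as
independent — in null simulations it rejected ~50% of data sets at the
nominal 5% level. It is kept for comparability, not for inference.

**PERMANOVA.** The distance matrix is Gower-centered,
G = C(−½ D∘D)C with C = I − 11ᵀ/n, whose trace is the total sum of
squares. For an ordered term list, cumulative treatment-coded design
matrices give orthonormal bases Q_k (via SVD with rank detection, so
aliased terms get df 0 and SS 0 rather than a crash — relevant when family
is nested in tolerance); SS_k = tr((H_k − H_{k−1})G) with H_k = Q_kQ_kᵀ,
SS_res = tr(G) − ΣSS_k, pseudo-F_k = (SS_k/df_k)/(SS_res/df_res), and df_k
is the rank increment. p-values count permutations (default 999, free
permutation; optional within-strata) whose recomputed F meets or exceeds
the observed one, with ties counted as exceedances (conservative) and the
identity permutation included: p = (1 + #{F* ≥ F})/(1 + n_perm). For
Euclidean distances this reproduces coordinate-space multivariate ANOVA
exactly (McArdle–Anderson identity), which the tests exploit as a
brute-force oracle; agreement with `vegan::adonis2` was verified to 9
decimals on a frozen fixture. Factors are treatment-coded with the first
(sorted) level as reference; interactions are element-wise products of the
main-effect columns. A factor can instead be coded as a single numeric
column (df 1) to mirror decompositions that treated a multi-level factor
that way; the default is the natural multi-df coding.

**Indicator values.** For feature i and group j, specificity is mean
abundance in j divided by the sum of group means, fidelity is the fraction
of samples in j where the feature is present, and IndVal = specificity ×
fidelity × 100. (Some published descriptions swap the two labels; the
product is identical either way, and this package follows the labdsv
convention.) The test statistic is max_j IndVal with a group-label
permutation null, default 1000 permutations; features absent everywhere get
IndVal 0 and p 1. A Holm adjustment across features is attached for
reference, but the raw permutation p is primary, matching how the analysis
is conventionally reported. The Monte-Carlo p was checked against
exhaustive label enumeration on small instances.

**Core microbiome and resilience.** The core is the set of features whose
prevalence among *individuals* strictly exceeds a threshold (default 0.5)
within the warm arm or within the cold arm. "Individual" means fish: a fish
is positive if the feature appears in either gut part, because prevalence
statements about individuals should not double-count body sites. The
either-arm rule is the default, with a both-arms mode exposed, since
published phrasings support both readings. Core counts are renormalized to
percentages summing to 100 within the core; per tolerance group, each core
feature's fold change is mean percent at cold ÷ mean percent at warm using
group-level means — warm and cold fish are different individuals
(full siblings), so no pairing exists. Zero warm means get a pseudo-value
of half the smallest nonzero renormalized abundance and are flagged.
Resilience is compared by a two-sided Wilcoxon rank-sum test on the
|log2 FC| distributions of the two groups (asymptotic by default, optional
Monte-Carlo label permutation).

**Microbiome–transcriptome linkage.** The microbiome side uses principal
coordinates of Bray–Curtis on the posterior-gut samples (one per fish); the
expression side uses PCA scores (centered SVD). Four components per side by
default — published analyses cite both four and five, so k is an explicit,
logged knob. Canonical correlations come from the SVD of Q_AᵀQ_B with Q's
orthonormal bases of the centered score matrices. The linkage statistic is
the Stewart–Love redundancy of A given B on the covariance scale,
tr(A_cᵀ P_B A_c)/tr(A_cᵀ A_c), which equals Σ_t ρ_t² f_t with f_t the
fraction of A's total variance carried by its t-th canonical variate. This
form was chosen because it is exactly 1 when B spans A, reduces to the
squared Pearson correlation at k = 1, and needs no standardization
convention; "total variance explained through all canonical variates" has
no single agreed formula, so the choice is recorded in output metadata. The
permutation null shuffles the row order of B only (breaking the sample
correspondence while leaving each block internally intact), default 1000
permutations. The transcriptome fold-change contrast mirrors the core
resilience statistic: per-gene group-mean cold/warm fold changes, rank-sum
test on |log2 FC| between tolerance groups.

## Synthetic data: what it emulates and what it does not

`generate_microbiome` draws, per sample, Dirichlet-multinomial counts
around a group × temperature composition; library sizes are
Poisson(20 000). Compositions are softmax of summed log-scale effects:

- a log-normal rank-abundance baseline (sd 2.0) — skewed communities with
  many rare taxa, as in real 16S data;
- 11 planted core taxa drawn from a narrow high-abundance band
  (N(3.5, 0.5) on the log scale) so their individual-level prevalence
  exceeds 50% in both arms by construction;
- a tolerance-group offset (sd 0.4) — host genetics select composition;
- family random intercepts (sd 0.15) — a nonzero variance component for the
  mixed-model stage to recover;
- a gut-part offset (sd 0.8) — the strong anterior/posterior difference;
- one shared cold-response direction z ~ N(0, I), applied at cold as
  δ_group · z with δ_resistant = 0.3 ≤ δ_sensitive = 1.0. A shared
  direction with group-specific magnitude is the structural statement
  "both hosts face the same stressor; the resistant host damps its effect",
  and it is what makes the tolerance × temperature interaction and the
  fold-change contrast identifiable rather than seed-lottery outcomes;
- 30% of non-core taxa absent at cold (lower cold richness), and a lower
  Dirichlet concentration at cold (100 vs 200) for stress-induced
  overdispersion;
- per-fish latent factors (4 dimensions) loading on composition
  (scale 0.4), shared with the expression generator.

`generate_expression` produces one profile per fish: log expression =
latent_loading × (latent scores × transcript loadings) + the shared
transcriptional cold response scaled by δ_group + N(0, 1) noise,
exponentiated to a positive scale. Setting `latent_loading=0` severs the
microbiome–expression link (the CCA null); setting both δ to 0, the
diversity drop to 0 and equal concentrations makes all samples exchangeable
(the global null used for calibration tests).

One global seed drives independent named streams for structure, counts and
expression, so regenerating one artifact never perturbs another.

The generator does **not** emulate: sequencing error, chimeras or primer
bias (counts are drawn, not reads); compositional correlation between taxa
beyond the latent factors; phylogenetic structure (no tree, hence no
UniFrac); zero-inflation beyond what the Dirichlet-multinomial and the
cold drop-out produce; or library-size confounding with condition. Passing
tests therefore certify the statistics and their calibration on a
plausible abundance model, not robustness to real-data artifacts.

## Numerical choices

- Rank detection in design matrices and CCA bases uses a relative singular
  value cutoff of 1e-9/1e-10 of the leading value.
- Permutation p-values always include the identity permutation and count
  ties as exceedances: p = (1 + #{T* ≥ T − 1e-12})/(1 + n_perm).
- Shannon of a single-feature sample is clamped to exactly 0 (avoiding
  −0.0); samples with zero totals are errors, not NaNs.
- PCoA eigenvalues within 1e-10 of zero (relative) are treated as null
  axes; negative mass is reported, never silently folded in.
- Pipeline stage seeds are derived from the global seed through named
  `SeedSequence` spawn keys and recorded in the report, so any stage can be
  reproduced in isolation.

## Problem sizes used by the test suite

Calibration tests run 200 null data sets per permutation test at 99
permutations on a reduced design (48 samples, 40 taxa); planted-signal
recovery runs 50 studies at full design scale with 99 PERMANOVA
permutations; CCA power runs 100 studies at 199 permutations. These sizes
give the binomial assertions (≥ 90% recovery) comfortable margins while
keeping the suite around half a minute.

## Known limitations

- Sequential (Type I) sums of squares only; marginal (Type III) tests and
  the multivariate dispersion test (betadisper) are out of scope.
- The mixed model supports a single random intercept; crossed or nested
  random effects (e.g., fish within family) are not fitted.
- The distance-contrast pair-pooling mode is anti-conservative by
  construction (see above) and should be used only to reproduce legacy
  analyses.
- CCA assumes more samples than total score dimensions; regularized or
  sparse variants are not provided.
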