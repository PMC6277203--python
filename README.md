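# thermogut

Statistical analysis of how host selection for cold tolerance shapes the gut
microbiome and buffers its response to temperature — built for two-factor
(host tolerance group × water temperature) fish challenge experiments that
pair 16S gut count tables with liver expression matrices.

The package is aimed at microbial-ecology analysts who need the full chain
of community statistics behind such a study as tested, reusable code:

- **α-diversity**: rarefaction (to a common depth, default 6000 reads),
  richness, Shannon H′, rarefaction curves, and a REML random-intercept
  mixed model (family as the random effect) for diversity responses.
- **β-diversity**: Bray–Curtis on counts, Jaccard on presence/absence,
  principal-coordinates ordination, and Monte-Carlo t contrasts between
  groups of pairwise distances.
- **PERMANOVA** (Adonis-style), written from scratch: sequential (Type I)
  sums of squares extracted from the Gower-centered matrix
  `G = C(−½ D∘D)C` via cumulative hat matrices,
  `SS_k = tr((H_k − H_{k−1})G)`, pseudo-F `(SS_k/df_k)/(SS_res/df_res)`,
  and p-values from joint row/column permutation of the distance matrix
  (999 permutations by default). Verified against `vegan::adonis2` and
  coordinate-space multivariate ANOVA.
- **Indicator values** (Dufrêne–Legendre): per feature and group,
  `IndVal = specificity × fidelity × 100` where specificity is the share of
  group mean abundance and fidelity the within-group prevalence, with a
  1000-permutation null on `max_group IndVal`.
- **Core-microbiome resilience**: taxa present in >50% of individuals in a
  temperature arm, renormalized to percentages within the core, per-group
  cold/warm fold changes, and a rank-sum contrast of |log2 FC| between
  tolerance groups.
- **Microbiome–transcriptome linkage**: principal coordinates of the gut
  community vs PCA scores of liver expression, canonical correlations, a
  Stewart–Love redundancy statistic (fraction of microbiome score variance
  explained through all canonical variates), and a permutation null that
  shuffles the sample correspondence (1000 permutations).
- **Synthetic study generator**: Dirichlet-multinomial counts over a
  2 groups × 3 families × 7 fish × 2 temperatures × 2 gut parts design with
  a shared cold-response direction attenuated in the resistant group,
  planted core taxa, family effects, and a latent factor linking microbiome
  composition to a generated expression matrix — so every statistic can be
  validated against known ground truth.

## Worked example

```python
from thermogut import (PipelineConfig, SyntheticConfig, run_pipeline)

report = run_pipeline(PipelineConfig(seed=1, synthetic=SyntheticConfig(seed=1)))

stages = report["stages"]
print(stages["alpha_diversity"]["mean_shannon"])
print(stages["beta_diversity"]["mean_warm_cold_distance"])
print(stages["core_resilience"]["median_abs_log2_fc"])
print({k: stages["cca"][k] for k in ("variance_explained", "permuted_mean", "p")})
```

prints (seed 1, canonical settings):

```
{'warm24': 4.056321034148736, 'cold12': 3.814359942821941}
{'resistant': 0.6416709183673469, 'sensitive': 0.7129349962207104}
{'resistant': 1.0948048473727248, 'sensitive': 1.8302323878800235}
{'variance_explained': 0.19912154255287134, 'permuted_mean': 0.049103610127041, 'p': 0.000999000999000999}
```

Reading the numbers: Shannon diversity drops from 4.06 to 3.81 bits after
cold exposure; the warm→cold compositional shift (mean Bray–Curtis between
warm and cold samples of the same group) is smaller in the resistant group
(0.64 vs 0.71), as is the median |log2 fold change| of the core microbiome
(1.09 vs 1.83) — the resistant microbiome is buffered. The microbiome and
expression ordinations share 19.9% of score variance versus 4.9% under
permutation (p ≈ 0.001), recovering the planted host–microbiome linkage.

The same analyses run from the shell:

```bash
thermogut generate --seed 1 --out-dir study/
thermogut permanova --table study/feature_table.tsv --meta study/metadata.tsv \
    --n-perm 999 --seed 1 --out permanova.tsv
thermogut run --seed 1 --out-dir runs/001     # full pipeline + report.json
```

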