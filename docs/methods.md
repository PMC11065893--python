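# Methods

## The model

`twaskit` tests whether the *genetically regulated* component of a molecular
phenotype — gene expression, 3'UTR alternative polyadenylation (quantified
as PDUI, the fraction of transcripts using the distal polyA site) or
exon-junction splicing (PSI, the fraction of reads supporting inclusion) —
is associated with a disease trait, using only GWAS summary statistics plus
a reference panel with both genotypes and molecular measurements.

The procedure has two stages.

**Stage 1 — cis prediction models.** For each feature *g*, all QC-passing
variants within ±500 kb of the feature's anchor are offered to an elastic
net fit on the covariate-residualized phenotype:

    min_w  (1/2n) ||y − Xw − b||² + λ (α ||w||₁ + (1−α)/2 ||w||₂²),  α = 0.5

λ is chosen by 5-fold cross-validation over a 100-point log-spaced grid
descending four orders of magnitude from λ_max (the `lambda.min` rule);
the cross-validated prediction R is the Pearson correlation between the
held-out fold predictions at `lambda.min` and the observed phenotype, the
single-level CV convention of `cv.glmnet`-style pipelines. Models with
R > 0.1 (strict) and at least one non-zero weight enter the weight
database. Genotype columns are standardized internally; exported weights
apply to raw 0–2 dosages.

**Stage 2 — summary-statistic gene-level test.** With w_lg the weight of
variant *l* in model *g*, β̂_l / se(β̂_l) the GWAS marginal effect and its
standard error, σ̂_l the reference-panel dosage SD and
σ̂_g = sqrt(wᵀΓw) the SD of the predicted level (Γ the reference-panel
covariance of the model variants, denominator n−1):

    Z_g = Σ_{l ∈ model_g} w_lg (σ̂_l / σ̂_g) (β̂_l / se(β̂_l))

with two-sided p from the standard normal. Per layer, m is the number of
models actually tested and the family-wise threshold is 0.05/m
(Bonferroni). Model variants missing from the GWAS are dropped and σ̂_g is
recomputed on the intersection; models losing more than half their
absolute weight mass are flagged. Replication of an externally reported
association uses the one-sided p = Φ(−Z·direction), significant at 0.05.

**Conditional analysis.** To ask whether a gene-level signal merely tags a
known risk variant, marginal GWAS effects are adjusted for the nearest
GWAS-significant lead variant (p < 5×10⁻⁸ within ±500 kb, nearest by
distance, ties by smaller p) using summary-statistic conditional algebra:
with D_j = n·Γ_jj and B = n·Γ approximating XᵀX,

    b_C = B_CC⁻¹ (D_C ∘ β̂_C),   β̃_t = β̂_t − D_t⁻¹ B_tC b_C,
    se(β̃_t) = sqrt(σ² / D_t)

with phenotypic variance σ² treated as fixed (1 for a standardized trait).
The gene-level statistic is then recomputed from the adjusted β̃, se. Two
properties worth knowing: (i) a variant conditioned on itself goes exactly
to zero; (ii) relative to the individual-level joint-OLS coefficient the
conditional estimator is shrunk by exactly (1 − r̂²_tC), so the two
estimands coincide when target and conditioning variant are in weak LD —
the conditional-oracle study probes that regime deliberately. For
case-control GWAS the same algebra is applied on the log-odds scale, which
is an approximation; the oracle studies use the simulator's
linear-on-liability mode, where the algebra is exact.

**Permutation test.** To ask whether the weights add information beyond
the raw variant-trait associations, the weight-to-variant assignment is
shuffled within the model (uniform random permutation) and |Z| recomputed;
empirical p = (1 + #{|Z_perm| ≥ |Z_obs|}) / (1 + n_perm), capped at 1000
permutations, entered only when the marginal p < 0.05, with adaptive early
stopping once 20 exceedances are seen (at that point p̂ ≳ 0.02 is already
resolved). Sign-flipping is available as an alternative scheme. Models
with fewer than 3 variants are reported as not evaluable.

## Phenotype preparation

* Expression: genes detected (TPM > 0) in ≤ 5% of samples are removed;
  values become log2(TPM + 1) — the pseudocount of 1 keeps zeros at zero.
* APA / junction events: events with > 5% missing quantifications are
  removed; surviving missing values are median-imputed per feature (the
  elastic net needs complete columns).
* Quantile normalization: the classic cross-sample rank-mean recipe —
  every sample receives the identical sorted value vector (per-rank mean
  over samples), ties by average rank. A per-feature inverse-normal
  dialect is available behind a flag. Normalization is skipped for
  single-feature matrices, where the cross-sample recipe degenerates to a
  constant.
* Hidden confounders: top-k principal components of the
  feature-standardized matrix, a deterministic surrogate for PEER latent
  factors; k defaults to 15 below 150 samples and 30 at or above (the
  GTEx sample-size rule). Signs are fixed by making each factor's
  largest-|loading| entry positive.
* Covariates (age, genotype PCs, latent factors) are residualized out of
  each feature before training, keeping the exported weights purely
  genotypic; they are not carried as unpenalized columns.

## Variant QC

Retain variants with MAF ≥ 5%, Hardy–Weinberg exact-test p ≥ 10⁻⁴,
missing rate ≤ 5%, imputation r² ≥ 0.8 (when present), biallelic, not
strand-ambiguous (A/T, C/G). All inequalities are strict on the failure
side: a variant exactly at a threshold passes. The HWE test is the exact
enumeration over heterozygote counts given the allele counts (two-sided by
summing tables no more probable than the observed one); a chi-square
alternative is available. For HWE only, dosages further than 0.1 from an
integer are left out of the genotype counts. Allele harmonization against
the weight database passes matching alleles through, negates β and
complements EAF for swapped alleles, and drops mismatches and ambiguous
pairs with a report.

## The synthetic cohort

The generator emulates the data-generating assumptions the pipeline is
built for, with known ground truth:

* **Genotypes.** Per haplotype, a Gaussian AR(1) latent chain over
  variants (adjacent latent correlation `ld_rho`, default 0.7) thresholded
  at Φ⁻¹(allele frequency); the two haplotype alleles sum to a hard-call
  dosage, giving Hardy–Weinberg proportions at the drawn frequency and
  tunable LD decay. Allele frequencies are uniform on `maf_range`
  (default 0.05–0.5); positions are near-uniform on one synthetic
  chromosome; feature anchors are evenly spaced (1 per Mb by default).
  Haplotype-based coalescent simulation was deliberately rejected as
  unnecessary for these studies.
* **Phenotypes.** Latent value = genetic + covariate + noise with unit
  variance; the genetic part is a small set of causal cis variants scaled
  so its variance equals `cis_h2` (default 0.3, a realistic bulk-tissue
  cis heritability); covariates (standardized age, a binary batch) carry
  10% of variance by default. Expression is 2^(latent + 5) (TPM-like);
  APA and junction layers push the latent value through a logit-linear
  binomial count model at Poisson depth 50, with totals below 10 reads
  set missing.
* **GWAS.** Liability = Σ_f α_f · standardized genetic value of feature f
  + Gaussian noise, total variance 1; cases are the top `case_fraction`
  (default 0.45) of liability. Marginal per-variant effects come from
  vectorised univariate logistic regression (Newton/IRLS), or from linear
  regression on the continuous liability when exact oracle algebra is
  needed. Reported EAF is exactly the cohort allele frequency.

What the generator does **not** emulate: realistic human LD maps and
recombination hotspots, admixture and population structure, imputation
error, genotyping batch effects, overlapping genes, trans effects, and
sample overlap between reference panel and GWAS (except where a study
constructs it on purpose). Passing tests therefore certify the statistics
and the code paths, not robustness to those real-data features.

## Study sizes and numerical choices

The validation battery (shared by the test suite and
`scripts/acceptance.py`) uses sizes chosen to give stable Monte-Carlo
estimates at desk scale:

* Oracle equivalence: one 2000-sample cohort serving as both panel and
  GWAS, 50 features, linear trait; max |ΔZ| is compared against 0.1.
* Conditional oracle: 20 scenarios at n = 2000, conditioning variants
  40–100 AR(1) steps from the target (latent r ≲ 0.015, so the
  (1 − r̂²) shrinkage is within the 2% tolerance).
* Mediated / independent conditioning: 20 replicates, 800-sample panel at
  cis-h² = 0.5, 6000-sample linear-trait GWAS, two features with disjoint
  cis windows.
* Null calibration: 1200 features in independent 100-feature LD blocks,
  150-sample panel at cis-h² = 0.3, 3000-sample case-control GWAS with no
  causal features.
* Permutation null: 250 features, entry threshold disabled and the full
  1000 permutations run so the p-values have resolution near 0.05.
* Locus ranking: 50 replicates of a 5-feature locus, 150-sample panel at
  cis-h² = 0.3, 8000-sample case-control GWAS with one mediating feature.

Numerical choices: Γ uses denominator n−1 with no regularization by
default (an optional 10⁻⁸ ridge guards σ_g² against floating-point
negativity); zero-variance variants are dropped from covariances with a
warning; held-out CV predictions carry the global phenotype mean rather
than fold-specific intercepts, because fold-mean intercepts anti-correlate
with held-out outcomes and bias the null cv-R negative by about
−sqrt(k/n); cv-R of constant predictions is defined as 0; monomorphic
variants are excluded from simulated summary statistics (their marginal
effect is undefined); coordinates are 1-based inclusive everywhere, with
BED converted on read.

## Known limitations

* The conditional se formula treats phenotypic variance as fixed; for
  logistic GWAS the whole conditional adjustment is a log-odds-scale
  approximation (as in common practice for summary-statistic conditioning
  of case-control traits).
* Bonferroni m counts models actually tested; features skipped for zero
  GWAS overlap are excluded from m and logged.
* The weight database stores only non-zero weights; a model whose weights
  are all zero is counted as "not predictable".
* No stepwise conditional model selection or fine-mapping; one lead
  variant (or an explicitly supplied conditioning set) per feature.
* lambda.min is used for λ selection; lambda.1se is not implemented.
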