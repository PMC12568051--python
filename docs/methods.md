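# Methods

## Scope

`gblupga` implements genomic prediction for repeated-record economic traits
in livestock (the motivating application is cashmere goat breeding) with a
GWAS-prior-weighted genomic relationship matrix — the GBLUP–GA / BLUP|GA
family of methods — including dominance effects and permanent-environment
effects, REML variance-component estimation, and five-fold cross-validated
prediction accuracy. A synthetic-data generator stands in for the
proprietary goat data, so the whole chain is testable offline.

## Model

Record-level animal model:

    y = Xb + Zu + Wp + Vd + e
    u ~ N(0, G σ²a),  p ~ N(0, I σ²p),  d ~ N(0, D σ²d),  e ~ N(0, I σ²e)

* `b`: fixed effects — intercept plus categorical flock, sex, age and
  measurement year (age is categorical, not a covariate). Reference-level
  (first sorted level) dropping keeps X full rank.
* `u`: additive genetic values (GEBV = û), `p`: permanent-environment
  effects (one per individual, shared by its records), `d`: dominance
  deviations, `e`: residual.
* `Z = W = V` share one record-to-individual incidence pattern.

### Relationship matrices

* Additive (VanRaden): `G = ZcZc′ / 2Σpᵢqᵢ` with `Zc = M − 2p`, `M` the
  0/1/2 count of the counted allele (pinned to PLINK allele-1 so G is
  reproducible), `p` the observed sample frequency.
* Dominance: the heterozygosity indicator `h ∈ {0,1}` centred by its
  Hardy–Weinberg expectation `2pⱼqⱼ`, with denominator `4Σpⱼ²qⱼ²`. This
  "hybrid" coding follows the published formula pair exactly, but note it is
  **not unit-scaled**: `E[(h−2pq)²] = 2pq(1−2pq)`, so the mean diagonal is
  `Σ2pq(1−2pq)/4Σp²q²` ≈ 1.47 for MAF ~ U(0.05, 0.5). Consequently σ²d
  estimates under this coding are deflated by roughly that factor. The
  pure dominance-deviation coding (Vitezica-style, scores −2p², 2pq, −2q²
  and denominator Σ(2pq)², unit mean diagonal) is available via
  `coding="dominance_deviation"`.
* Missing genotypes are mean-imputed (code `2pᵢ`) after QC, so imputed
  entries contribute exactly zero to the centred scores.
* Subset matrices (built from a few hundred SNPs) are rank-deficient; any
  matrix destined for inversion receives a ridge of
  `1e-6 × mean(diagonal)` by default, recorded on the object.

### GWAS-prior weighting (GBLUP–GA)

SNPs are ranked by GWAS p-value; the top fraction (5/10/15/20%) forms the
prior set, the rest the residual set. The prior count is
`floor(fraction × n)`: the published counts for a 50,728-SNP panel
(2,536 / 5,073 / 7,609 / 10,145) are mutually inconsistent under any single
rounding rule, and floor reproduces three of the four. Ties are broken by
(chromosome, position, SNP id) so selection is order-invariant.

Two **separate** REML fits — one with (G1, D1) only, one with (G2, D2)
only, each with the full fixed and permanent-environment structure — give
the partition genetic variances, and

    τ = (σ²Ga1 + σ²Gd1) / (σ²Ga1 + σ²Gd1 + σ²Ga2 + σ²Gd2)

weights the combined matrices `Gt = τG1 + (1−τ)G2` and `Dt = τD1 + (1−τ)D2`.
Separate fits were chosen because the published tables report distinct
permanent-environment and residual estimates per matrix set, which a joint
fit cannot produce; the original BLUP|GA literature fits jointly, which
remains available via `fit_partition_models(..., joint=True)` (both matrix
sets as separate random effects in one model). Dominance
matrices are split and combined with the same τ as the additive ones, since
the published tables report dominance variances per partition.
Floor-pinned components enter the τ formula at their floor value; if all
four components are exactly zero, τ defaults to 0.5 with a warning.
The final prediction model refits all variance components with (Gt, Dt).

### REML

Average-information REML with EM fallback, implemented in the phenotypic
covariance form `V = Z K Z′ + σ²e I`, `K = σ²a G + σ²d D + σ²p I`. The
Woodbury identity reduces every solve to the individual dimension (one LU
factorisation of `σ²e I + R K` per evaluation, `R` the diagonal of record
counts), so fits with thousands of records take well under a second.

Numerical policy:

* Variance floor `1e-8 × var(y)`; components that hit it are pinned and
  excluded from the AI system while their gradient points outward. This
  reproduces the near-zero boundary estimates (1e-7-ish) that commercial
  REML software prints for such data.
* Step control: first iteration EM; an AI step whose likelihood drops is
  halved up to four times, then replaced by EM. EM steps never decrease
  the restricted likelihood.
* Convergence: relative log-likelihood change below `tol` (default 1e-8;
  the cross-validation loop uses 1e-6), **accepted only after a full
  undamped AI step**. Damped/EM steps can creep geometrically along weakly
  identified ridges (e.g. σ²a vs σ²p trade-offs under a misspecified
  residual-set matrix) with per-iteration gains below any tolerance, which
  would otherwise declare convergence several log-likelihood units short
  of the optimum — observed in practice, hence this rule.
* If the AI/EM loop has not converged after `stall_iter` (default 15)
  iterations, the fit switches to L-BFGS-B on log-variances with the exact
  analytic gradient, which handles those ridges in a few dozen
  evaluations.
* A true boundary component (generating σ²p = 0) is estimated at the floor
  in roughly half of replicates and small-positive in the rest — the
  standard half-normal boundary law — so recovery tests assert that
  pattern, not universal pinning.

### Mixed-model equations

Henderson's block system with ratios `α₁ = σ²e/σ²a`, `α₂ = σ²e/σ²p`,
`α₃ = σ²e/σ²d`; terms excluded by the model spec (or whose variance sits at
the floor) drop out of the system. Individuals present in G without records
are carried in the equations and predicted through G⁻¹ — this is how
validation individuals get GEBVs. The solver is verified against the
closed-form conditional-expectation/GLS oracle on random toys to 1e-8.

### Genetic parameters

`h²a = σ²a/σ²T`, `h²d = σ²d/σ²T`, repeatability
`r = (σ²a+σ²d+σ²p)/σ²T`, `σ²T` the component sum.

### Cross-validation

Folds are assigned per individual (never per record). Per fold, everything
downstream of the raw data — GWAS scan, partition, partition fits, τ,
weighted matrices, component refit, MME — uses training records only;
validation individuals appear in the matrices but carry no records.
Accuracy compares validation GEBVs with adjusted phenotypes (records minus
training-estimated fixed effects, averaged per individual). Two
conventions are always computed:

* `cor_over_h` (default): `corr(adjusted, GEBV)/√h²` — the field's usual
  definition; `h²` is the additive heritability from that fold's training
  fit.
* `literal_cov_over_h2`: `cov(adjusted, GEBV)/h²` — the formula as printed
  in the published analysis; it is scale-dependent and can exceed 1, and is
  reported for comparability only.

When p-values are supplied externally they are reused across folds with a
logged leakage caveat (the motivating study's situation, where the GWAS
predates the prediction experiment); the synthetic default recomputes the
scan within each training fold.

Scenario comparison is a one-way ANOVA of fold-level accuracy on scenario
(statsmodels OLS + anova_lm).

## Synthetic data

The generator emulates: ~2,299 individuals × ~50,728 chip SNPs (defaults
scaled to 500 × 5,000; `SimulationConfig.full_scale()` restores full
size), 2–5 records per individual (the published ratio is ≈4.2
records/individual), four categorical fixed effects, and variance regimes
matching the published weighted-matrix estimates for the four traits
(`TRAIT_REGIMES`: e.g. cashmere yield σ²a = 9,672.55, σ²d = 2,049.59,
σ²p ≈ 0, σ²e = 26,699.68).

Choices where the source is silent:

* Genotypes are independent SNPs under Hardy–Weinberg proportions with
  MAF ~ U(0.05, 0.5); an optional Markov block scheme (`ld_block_size`,
  `ld_rho`) adds within-block LD, since prior-set selection is more
  realistic with LD.
* QTL effects are drawn normal and rescaled so realized genetic variances
  across the simulated individuals equal their targets exactly (sample
  variance, ddof = 1) — recovery tests then have a fixed truth.
* Fixed-effect level values are equally spaced offsets spanning one
  residual SD; flock and sex are individual-constant, age and year vary by
  record.
* Records per individual are uniform on {2,…,5}.

What a green test does **not** establish: the generator has no pedigree
structure, selection, genotyping error, or realistic LD decay, and its
GWAS stand-in ignores relatedness — so absolute accuracies here do not
transfer to real populations; only the *relative* behaviour of the
weighting scheme is probed.

## Known limitations

* The real goat data are private; published real-data accuracies
  (0.8156/0.8361/0.7571/0.8074) are context, not targets.
* Standard errors of variance components come from the inverse AI matrix
  at convergence (no delta-method SEs for heritabilities).
* The stand-in GWAS is a fixed-effect single-SNP scan (additive code +
  heterozygosity indicator, F-test); it exists to produce ordered
  p-values, not to be a polygenic-controlled GWAS.
* No multi-bin (>2 SNP class) weighting and no per-SNP weights; those are
  different methods (wGBLUP/WssGBLUP).
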