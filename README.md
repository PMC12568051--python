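# gblupga

Genomic prediction for repeated-record economic traits with a
GWAS-prior-weighted genomic relationship matrix (GBLUP–GA), including
dominance and permanent-environment effects.

## The problem

Standard GBLUP assumes every SNP contributes equally to a trait: breeding
values are predicted from an additive genomic relationship matrix
`G = ZZ′/2Σpq` built from the whole panel. When a prior GWAS says some
markers matter much more, that information can be folded into the
relationship structure instead of being ignored. GBLUP–GA (a BLUP|GA
variant) does this by splitting the panel into a *prior* set (the top
5–20% of SNPs by GWAS p-value) and a *residual* set, estimating how much
genetic variance each set carries, and re-weighting:

    τ  = (σ²Ga1 + σ²Gd1) / (σ²Ga1 + σ²Gd1 + σ²Ga2 + σ²Gd2)
    Gt = τ·G1 + (1−τ)·G2        (and Dt likewise for dominance)

The package implements the full chain for a repeated-record animal model

    y = Xb + Zu + Wp + Vd + e,   u ~ N(0, G σ²a), p ~ N(0, I σ²p),
                                 d ~ N(0, D σ²d), e ~ N(0, I σ²e)

with categorical fixed effects (flock, sex, age, measurement year),
AI-REML variance components, Henderson's mixed-model equations, and
five-fold cross-validated prediction accuracy per prior-information
scenario. It is aimed at animal-breeding researchers who want a tested,
scriptable reference implementation of the weighting scheme — the
motivating application is cashmere goat breeding (cashmere yield/diameter/
length, body weight), and a synthetic-data generator emulating that kind
of dataset makes every stage testable without access to proprietary
records. See `docs/methods.md` for the model details and numerical policy.

## Worked example

End-to-end on synthetic data: a cashmere-yield-like trait (σ²a = 9,672.55,
σ²d = 2,049.59, σ²p ≈ 0, σ²e = 26,699.68) with 20 QTLs on a 2,000-SNP,
400-individual panel; scenarios "none" (plain GBLUP) and "top5" (GBLUP–GA
with the top 5% of SNPs from a within-fold GWAS scan as prior):

```python
from gblupga import Pipeline, RunConfig

cfg = RunConfig.default(
    out_dir="demo_run", seed=42,
    simulation={"n_individuals": 400, "n_snps": 2000, "n_qtl": 20,
                "regime": "CY"},
    scenarios=["none", "top5"],
)
summary = Pipeline(cfg).all()
```

which logs (amongst other artifacts written under `demo_run/`):

```
scenario top5: tau=1.000
cv none: mean accuracy 0.3567 (sd 0.3555)
cv top5: mean accuracy 1.1001 (sd 0.2098)
```

and `demo_run/components.csv` holds the variance-component table (rows G,
G1, G2, Gt per scenario, mirroring how such analyses are usually
tabulated):

```
prior_fraction matrix  sigma_a2  sigma_d2  sigma_p2  sigma_e2  h2_additive  repeatability   tau
          none      G  6025.329     0.001  2760.210 28697.821        0.161          0.234
          top5     G1  5406.235  1487.816     0.001 26237.187        0.163          0.208  1.00
          top5     G2     1.604     0.984  8896.945 28670.712        0.000          0.237  0.00
          top5     Gt  5404.949  1487.694     0.001 26236.947        0.163          0.208
```

Reading this: the prior-set fit (G1) absorbs essentially all genetic
variance (τ ≈ 1.0 — with only 20 large-effect QTLs the scan finds them
all), so `Gt ≈ G1` and cross-validated accuracy rises from 0.36 to 1.10
(accuracy is `corr(adjusted phenotype, GEBV)/√h²`, which can exceed 1 when
the training fit underestimates h²; the raw correlation is reported
alongside). The scenario contrast is significant (ANOVA on fold
accuracies: F = 16.2, p = 0.0038). With many small-effect QTLs, τ lands in
the 0.5–0.8 range instead and the gain shrinks — the weighting only helps
when the prior is genuinely informative, which the test suite checks both
ways (informative prior vs shuffled p-values).

The same stages are scriptable from the shell:

```bash
gblupga print-config > config.yaml   # edit as needed
gblupga all --config config.yaml --seed 42 --out demo_run
gblupga gwas --config config.yaml    # or run stages individually:
gblupga partition --config config.yaml --fraction 0.05
gblupga cv --config config.yaml
```

## Acceptance script

`scripts/acceptance.py` recomputes, at run time via the package's τ
formula, the prior-set share of total genetic variance for three published
worked examples (cashmere yield top-5%, body weight top-5%, cashmere
length top-20%) from their printed partition variance components, and
writes them as JSON percentages:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
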