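"""SNP ranking by GWAS p-value and top-fraction prior-set selection.

The prior marker set is the first ``floor(fraction * n)`` SNPs after
sorting ascending by p-value (ties broken by chromosome, position, then
SNP id, so selection is invariant to input row order).  A minimal
single-SNP additive+dominance scan is included so synthetic end-to-end
runs are self-contained; externally supplied p-value tables are the
expected production input.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "SnpPartition",
    "select_top_fraction",
    "run_ad_gwas",
    "read_pvalues",
    "write_pvalues",
    "write_partition",
]

PVALUE_COLUMNS = ["snp_id", "chrom", "pos", "p_value"]


@dataclasses.dataclass
class SnpPartition:
    """Disjoint cover of the panel into prior and residual marker sets."""

    fraction: float
    prior_ids: list
    residual_ids: list

    @property
    def n_prior(self) -> int:
        return len(self.prior_ids)

    @property
    def n_residual(self) -> int:
        return len(self.residual_ids)

    def summary(self) -> dict:
        return {
            "fraction": self.fraction,
            "n_prior": self.n_prior,
            "n_residual": self.n_residual,
        }


def _validate_pvalues(pvals: pd.DataFrame) -> pd.DataFrame:
    missing_cols = set(PVALUE_COLUMNS) - set(pvals.columns)
    if missing_cols:
        raise ValueError(f"p-value table missing columns {sorted(missing_cols)}")
    bad = pvals["p_value"].isna() | (pvals["p_value"] <= 0) | (pvals["p_value"] > 1)
    if bad.any():
        raise ValueError(
            "invalid or missing p-values for SNPs: "
            f"{list(pvals.loc[bad, 'snp_id'].head(10))}"
        )
    if pvals["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP ids in p-value table")
    return pvals


def select_top_fraction(pvals: pd.DataFrame, fraction: float) -> SnpPartition:
    """Extract the top ``fraction`` of SNPs by ascending p-value.

    With the published 50,728-SNP panel this yields 2,536 / 5,072 / 7,609 /
    10,145 prior SNPs at 5/10/15/20% (floor rule).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    pvals = _validate_pvalues(pvals)
    n = len(pvals)
    n_prior = math.floor(fraction * n)
    if n_prior == 0:
        raise ValueError(f"fraction {fraction} selects zero of {n} SNPs")
    ordered = pvals.sort_values(
        ["p_value", "chrom", "pos", "snp_id"], kind="mergesort"
    )
    ids = ordered["snp_id"].to_list()
    return SnpPartition(
        fraction=fraction, prior_ids=ids[:n_prior], residual_ids=ids[n_prior:]
    )


def run_ad_gwas(
    geno: GenotypeMatrix, pheno: pd.DataFrame, covariates=("flock", "sex", "age", "year")
) -> pd.DataFrame:
    """Single-SNP additive+dominance scan on fixed-effect-adjusted means.

    Records are adjusted by OLS on the categorical covariates and averaged
    per individual; each SNP's model [1, allele count, heterozygosity] is
    compared to the intercept-only model by an F-test.  This is a ranking
    device for synthetic runs, not a relatedness-corrected GWAS.
    Monomorphic SNPs get p=1.
    """
    pheno = pheno[pheno["individual_id"].isin(geno.individual_ids)]
    genotyped = set(geno.individual_ids)
    orphans = set(pheno["individual_id"]) - genotyped
    if orphans:
        raise ValueError(f"phenotyped individuals not genotyped: {sorted(orphans)[:5]}")

    cov = [c for c in covariates if c in pheno.columns]
    y = pheno["value"].to_numpy(dtype=float)
    if cov:
        Xf = pd.get_dummies(pheno[cov].astype(str), drop_first=True, dtype=float)
        Xf.insert(0, "intercept", 1.0)
        Xm = Xf.to_numpy()
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid = y - Xm @ beta
    else:
        resid = y - y.mean()
    adj = (
        pd.DataFrame({"individual_id": pheno["individual_id"], "r": resid})
        .groupby("individual_id", sort=False)["r"]
        .mean()
    )
    has_pheno = set(adj.index)
    pos = {iid: i for i, iid in enumerate(geno.individual_ids)}
    ids = [i for i in geno.individual_ids if i in has_pheno]
    yv = adj.loc[ids].to_numpy()
    rows = [pos[i] for i in ids]
    codes = geno.codes[rows]
    n = len(yv)
    if n < 4:
        raise ValueError("need at least 4 phenotyped+genotyped individuals")

    yc = yv - yv.mean()
    syy = float(yc @ yc)
    a = codes - codes.mean(axis=0)
    h = (codes == 1.0).astype(float)
    h -= h.mean(axis=0)
    saa = np.einsum("ij,ij->j", a, a)
    shh = np.einsum("ij,ij->j", h, h)
    sah = np.einsum("ij,ij->j", a, h)
    say = yc @ a
    shy = yc @ h

    det = saa * shh - sah**2
    p_out = np.ones(geno.n_snps)
    # full-rank 2-predictor case
    full = det > 1e-10 * np.maximum(saa * shh, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_a = (shh * say - sah * shy) / det
        beta_h = (saa * shy - sah * say) / det
        ss_exp2 = beta_a * say + beta_h * shy
        f2 = (ss_exp2 / 2.0) / ((syy - ss_exp2) / (n - 3))
        p2 = stats.f.sf(f2, 2, n - 3)
        # additive-only fallback (h collinear with a, e.g. only codes {0,1})
        ss_exp1 = say**2 / saa
        f1 = ss_exp1 / ((syy - ss_exp1) / (n - 2))
        p1 = stats.f.sf(f1, 1, n - 2)
    single = (~full) & (saa > 1e-12)
    p_out[full] = p2[full]
    p_out[single] = p1[single]
    p_out = np.clip(np.nan_to_num(p_out, nan=1.0), np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chrom": geno.snp_chrom,
            "pos": geno.snp_pos,
            "p_value": p_out,
        }
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_pvalues(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", dtype={"snp_id": str, "chrom": str})
    return _validate_pvalues(df[PVALUE_COLUMNS])


def write_pvalues(pvals: pd.DataFrame, path) -> None:
    pvals[PVALUE_COLUMNS].to_csv(Path(path), sep="\t", index=False)


def write_partition(part: SnpPartition, prefix) -> None:
    """Two SNP-id list files plus a JSON count summary."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    Path(f"{prefix}.prior.txt").write_text("\n".join(part.prior_ids) + "\n")
    Path(f"{prefix}.residual.txt").write_text("\n".join(part.residual_ids) + "\n")
    Path(f"{prefix}.json").write_text(json.dumps(part.summary(), indent=1))
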