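"""Synthetic goat-like data: genotypes, trait architectures, repeated records.

The generator emulates the structure of a cashmere-goat breeding dataset:
~2,300 individuals on a ~50k SNP chip with 2-5 repeated records per
individual, four categorical fixed effects (flock, sex, age, measurement
year), and additive + dominance + permanent-environment + residual variance
regimes matching the published component estimates for cashmere yield (CY),
cashmere diameter (CD), body weight (BW) and cashmere length (CL).
Defaults are scaled down (500 individuals x 5,000 SNPs) so test runs stay
fast; ``SimulationConfig.full_scale()`` restores the full dimensions.

QTL effects are rescaled so the realized additive- and dominance-genotypic
variances across the simulated individuals equal the targets *exactly*
(sample variance, ddof=1), giving downstream recovery tests a fixed truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TraitArchitecture",
    "TRAIT_REGIMES",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_phenotypes",
    "write_phenotypes",
    "read_phenotypes",
]

# Published variance-component regimes (sigma_a2, sigma_d2, sigma_p2,
# sigma_e2) for the weighted-matrix fits of the four traits.
TRAIT_REGIMES: dict[str, tuple[float, float, float, float]] = {
    "CY": (9672.55, 2049.59, 4.40e-7, 26699.68),
    "CD": (0.161, 3.87e-7, 4.71e-8, 0.381),
    "BW": (8.96, 1.99e-6, 3.22, 17.23),
    "CL": (0.112, 0.0, 3.79e-6, 0.928),
}


class SimulationError(RuntimeError):
    pass


@dataclasses.dataclass
class SimulationConfig:
    """Dimensions and design of a synthetic dataset.

    records_per_individual is an inclusive integer range; the default (2, 5)
    averages ~3.5 records, bracketing the ~4.2 records/individual of the
    motivating goat data.
    """

    n_individuals: int = 500
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 100
    records_per_individual: tuple[int, int] = (2, 5)
    fixed_effect_levels: dict = dataclasses.field(
        default_factory=lambda: {"flock": 5, "sex": 2, "age": 7, "year": 5}
    )
    mu: float = 0.0
    ld_block_size: int = 1  # 1 = independent SNPs; >1 = Markov blocks
    ld_rho: float = 0.9  # within-block allele-copying probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0 or self.n_qtl <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        rlo, rhi = self.records_per_individual
        if not (1 <= rlo <= rhi):
            raise ValueError("records_per_individual must be a positive range")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    @classmethod
    def full_scale(cls, **kw) -> "SimulationConfig":
        """Full published dimensions: 2,299 individuals x 50,728 SNPs."""
        kw.setdefault("n_individuals", 2299)
        kw.setdefault("n_snps", 50728)
        return cls(**kw)


@dataclasses.dataclass
class TraitArchitecture:
    """True genetic architecture of a simulated trait."""

    qtl_indices: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    target_sigma_a2: float
    target_sigma_d2: float
    target_sigma_p2: float
    target_sigma_e2: float
    true_breeding_values: np.ndarray
    true_dominance_values: np.ndarray

    @property
    def qtl_ids(self):
        return self._qtl_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "qtl_index": self.qtl_indices,
                "additive_effect": self.additive_effects,
                "dominance_effect": self.dominance_effects,
            }
        )


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw genotypes under Hardy-Weinberg proportions, no missingness.

    Per-SNP allele frequencies are uniform on ``maf_range``.  With
    ``ld_block_size > 1`` the two haplotypes of each individual are Markov
    chains within blocks: the allele at SNP j copies the allele at j-1 with
    probability ``ld_rho`` (re-drawn from its own frequency otherwise),
    giving blocks of positively correlated SNPs.
    """
    rng = np.random.default_rng(config.seed)
    n, s = config.n_individuals, config.n_snps
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=s)
    if config.ld_block_size == 1:
        codes = rng.binomial(2, p[None, :], size=(n, s)).astype(float)
    else:
        haps = np.empty((2 * n, s), dtype=np.int8)
        for j in range(s):
            fresh = rng.random(2 * n) < p[j]
            if j % config.ld_block_size == 0:
                haps[:, j] = fresh
            else:
                copy = rng.random(2 * n) < config.ld_rho
                haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
        codes = (haps[0::2] + haps[1::2]).astype(float)
    snp_ids = [f"snp{j:06d}" for j in range(s)]
    return GenotypeMatrix(
        individual_ids=[f"ind{i:05d}" for i in range(n)],
        snp_ids=snp_ids,
        snp_chrom=np.array(["1"] * s),
        snp_pos=np.arange(1, s + 1) * 1000,
        codes=codes,
    )


def _rescaled_scores(raw: np.ndarray, target: float, label: str) -> tuple[np.ndarray, float]:
    """Centre ``raw`` and rescale so its sample variance equals ``target``."""
    centred = raw - raw.mean()
    v = float(np.var(centred, ddof=1))
    if target == 0.0:
        return np.zeros_like(centred), 0.0
    if v <= 0.0:
        raise SimulationError(
            f"zero genotypic variance at the sampled QTLs ({label}); "
            "cannot rescale to a positive target"
        )
    scale = np.sqrt(target / v)
    return centred * scale, scale


def simulate_trait(
    geno: GenotypeMatrix,
    n_qtl: int,
    sigma_a2: float,
    sigma_d2: float = 0.0,
    sigma_p2: float = 0.0,
    sigma_e2: float = 1.0,
    seed: int = 0,
    qtl_indices=None,
) -> TraitArchitecture:
    """Sample QTLs and effects; rescale to the target variances exactly.

    ``qtl_indices`` pins the causal SNPs (used to plant QTLs inside a prior
    marker set); by default they are drawn uniformly from polymorphic SNPs.
    """
    if n_qtl > geno.n_snps:
        raise ValueError("n_qtl exceeds panel size")
    if min(sigma_a2, sigma_d2, sigma_p2, sigma_e2) < 0:
        raise ValueError("target variances must be non-negative")
    rng = np.random.default_rng(seed)
    p = geno.allele_freq
    if qtl_indices is None:
        poly = np.flatnonzero((p > 0.0) & (p < 1.0))
        if poly.size < n_qtl:
            raise SimulationError("not enough polymorphic SNPs for the QTL count")
        qtl = np.sort(rng.choice(poly, size=n_qtl, replace=False))
    else:
        qtl = np.sort(np.asarray(qtl_indices))
        if qtl.size != n_qtl:
            raise ValueError("qtl_indices length must equal n_qtl")

    a_raw = rng.standard_normal(n_qtl)
    d_raw = rng.standard_normal(n_qtl)
    M = geno.codes[:, qtl]
    H = (M == 1.0).astype(float)

    tbv, a_scale = _rescaled_scores(M @ a_raw, sigma_a2, "additive")
    tdv, d_scale = _rescaled_scores(H @ d_raw, sigma_d2, "dominance")

    arch = TraitArchitecture(
        qtl_indices=qtl,
        additive_effects=a_raw * a_scale,
        dominance_effects=d_raw * d_scale,
        target_sigma_a2=sigma_a2,
        target_sigma_d2=sigma_d2,
        target_sigma_p2=sigma_p2,
        target_sigma_e2=sigma_e2,
        true_breeding_values=tbv,
        true_dominance_values=tdv,
    )
    arch._qtl_ids = [geno.snp_ids[j] for j in qtl]
    return arch


def simulate_phenotypes(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    config: SimulationConfig,
    trait: str = "trait",
) -> pd.DataFrame:
    """Repeated records: mu + fixed effects + g_a + g_d + pe + e.

    Fixed-effect level values are equally spaced offsets spanning one
    residual standard deviation (the data give no effect magnitudes).
    Flock and sex are constant within individual; age and year vary by
    record.  Returns a record-level table with columns individual_id,
    trait, value, flock, sex, age, year, plus the true genetic values
    repeated per record (true_bv, true_dv) for downstream truth checks.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = geno.n_individuals
    if len(arch.true_breeding_values) != n:
        raise ValueError("architecture was built on a different genotype matrix")
    rlo, rhi = config.records_per_individual
    n_rec = rng.integers(rlo, rhi + 1, size=n)
    sd_e = np.sqrt(arch.target_sigma_e2)

    level_values = {}
    for factor, L in config.fixed_effect_levels.items():
        level_values[factor] = (
            np.linspace(-0.5, 0.5, L) * sd_e if L > 1 else np.zeros(1)
        )

    pe = rng.normal(0.0, np.sqrt(arch.target_sigma_p2), size=n)
    ind_levels = {
        f: rng.integers(0, len(level_values[f]), size=n) for f in ("flock", "sex")
        if f in level_values
    }

    rows = []
    for i, iid in enumerate(geno.individual_ids):
        for _ in range(n_rec[i]):
            levels = {}
            fixed = 0.0
            for factor, vals in level_values.items():
                if factor in ind_levels:
                    lev = ind_levels[factor][i]
                else:
                    lev = rng.integers(0, len(vals))
                levels[factor] = lev
                fixed += vals[lev]
            value = (
                config.mu
                + fixed
                + arch.true_breeding_values[i]
                + arch.true_dominance_values[i]
                + pe[i]
                + rng.normal(0.0, sd_e)
            )
            rows.append(
                {
                    "individual_id": iid,
                    "trait": trait,
                    "value": value,
                    **{f: f"{f[0]}{lev}" for f, lev in levels.items()},
                    "true_bv": arch.true_breeding_values[i],
                    "true_dv": arch.true_dominance_values[i],
                }
            )
    return pd.DataFrame(rows)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    cols = ["individual_id", "trait", "value", "flock", "sex", "age", "year"]
    keep = [c for c in cols if c in pheno.columns]
    pheno[keep].to_csv(Path(path), index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), dtype={"individual_id": str})
    for col in ("individual_id", "value"):
        if col not in df.columns:
            raise ValueError(f"phenotype table missing required column {col!r}")
    return df
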