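"""Five-fold cross-validation of genomic prediction accuracy.

Folds are assigned by individual (never by record — repeated records of one
individual would otherwise straddle training and validation).  Per fold the
whole GBLUP-GA chain runs on training records only: GWAS (when p-values are
not supplied), top-fraction partition, partitioned REML fits, tau, weighted
matrices, a refit of the variance components with (Gt, Dt), and one MME
solve in which validation individuals are present in the relationship
matrix but carry no records.  Accuracy compares the validation individuals'
GEBVs with their adjusted phenotypes (records minus training-estimated
fixed effects, averaged per individual).

Two accuracy conventions are computed side by side: correlation divided by
the square root of heritability (the field's usual definition, the
default), and the literal covariance divided by heritability.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .grm import RelationshipMatrix, build_additive_grm, build_dominance_grm, regularize
from .mixed_model import (
    DesignSet,
    ModelSpec,
    RemlOptions,
    build_design,
    fixed_effect_part,
    genetic_parameters,
    reml_estimate,
    solve_mme,
)
from .partition import run_ad_gwas, select_top_fraction
from .weighting import build_weighted_set, fit_partition_models

__all__ = [
    "FoldAssignment",
    "CVOptions",
    "CVReport",
    "assign_folds",
    "adjusted_phenotypes",
    "prediction_accuracy",
    "run_cv",
    "compare_scenarios",
    "scenario_fraction",
    "plot_accuracy",
]

SCENARIO_FRACTIONS = {
    "none": None,
    "top5": 0.05,
    "top10": 0.10,
    "top15": 0.15,
    "top20": 0.20,
}


def scenario_fraction(scenario) -> float | None:
    """Map a scenario label ('none', 'top5', ... or a float) to a fraction."""
    if isinstance(scenario, str):
        if scenario not in SCENARIO_FRACTIONS:
            raise ValueError(f"unknown scenario {scenario!r}")
        return SCENARIO_FRACTIONS[scenario]
    f = float(scenario)
    if not 0.0 < f < 1.0:
        raise ValueError("scenario fraction must lie in (0, 1)")
    return f


@dataclasses.dataclass
class FoldAssignment:
    k: int
    assignment: dict  # individual id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [iid for iid, f in self.assignment.items() if f == fold]


def assign_folds(individual_ids, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniform random partition into k folds with sizes differing by <=1."""
    ids = list(individual_ids)
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} individuals into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {}
    for fold, chunk in enumerate(np.array_split(perm, k)):
        for i in chunk:
            assignment[ids[i]] = fold
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


@dataclasses.dataclass
class CVOptions:
    k: int = 5
    seed: int = 0
    ridge: float = 1e-6
    accuracy_method: str = "cor_over_h"  # or "literal_cov_over_h2"
    dominance_coding: str = "hybrid"
    reml: RemlOptions = dataclasses.field(default_factory=lambda: RemlOptions(tol=1e-6))
    gwas_covariates: tuple = ("flock", "sex", "age", "year")


@dataclasses.dataclass
class CVReport:
    scenario: str
    fold_accuracy: list
    fold_accuracy_literal: list
    fold_h2: list
    fold_tau: list
    method: str
    k: int
    seed: int
    fold_details: list = dataclasses.field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.nanstd(self.fold_accuracy, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "fold": np.arange(self.k),
                "accuracy": self.fold_accuracy,
                "accuracy_literal": self.fold_accuracy_literal,
                "h2": self.fold_h2,
                "tau": [np.nan if t is None else t for t in self.fold_tau],
                "method": self.method,
            }
        )


def adjusted_phenotypes(
    pheno: pd.DataFrame, b_hat: pd.Series, design: DesignSet
) -> pd.Series:
    """Records minus training-estimated fixed effects, averaged per individual.

    Records whose factor level was unseen in training are dropped with a
    warning.
    """
    fitted, ok = fixed_effect_part(pheno, design, b_hat)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} record(s) with factor levels unseen "
            "in training"
        )
    adj = pheno["value"].to_numpy(dtype=float) - fitted
    df = pd.DataFrame(
        {"individual_id": pheno["individual_id"].to_numpy()[ok], "adj": adj[ok]}
    )
    return df.groupby("individual_id", sort=False)["adj"].mean()


def prediction_accuracy(
    adjusted: pd.Series,
    gebv: pd.Series,
    h2: float,
    method: str = "cor_over_h",
) -> float:
    """Validation accuracy under the chosen convention.

    cor_over_h: correlation(adjusted, gebv) / sqrt(h2).
    literal_cov_over_h2: covariance(adjusted, gebv) / h2 (the printed form;
    scale-dependent, reported for comparability).
    """
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    common = adjusted.index.intersection(gebv.index)
    if len(common) < 3:
        raise ValueError("need at least 3 validation individuals")
    a = adjusted.loc[common].to_numpy(dtype=float)
    g = gebv.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0.0 or np.std(g) == 0.0:
        return float("nan")
    if method == "cor_over_h":
        return float(np.corrcoef(a, g)[0, 1] / np.sqrt(h2))
    if method == "literal_cov_over_h2":
        return float(np.cov(a, g, ddof=1)[0, 1] / h2)
    raise ValueError(f"unknown accuracy method {method!r}")


class _GrmCache:
    """Whole-panel centred scores and cross-products, computed once.

    Partition matrices follow from the disjoint-cover identity
    Z Z' = Z_prior Z_prior' + Z_residual Z_residual', so each fold's
    (G1, G2, D1, D2) costs one small cross-product instead of four
    whole-panel ones.
    """

    def __init__(self, geno: GenotypeMatrix, use_dom: bool, coding: str):
        self.ids = list(geno.individual_ids)
        self.col = {s: j for j, s in enumerate(geno.snp_ids)}
        p = geno.allele_freq
        q = 1.0 - p
        self.Zc = geno.codes - 2.0 * p[None, :]
        self.wa = 2.0 * p * q  # per-SNP additive denominator contribution
        self.Ka = self.Zc @ self.Zc.T
        self.Vc = None
        if use_dom:
            het = (geno.codes == 1.0).astype(float)
            frac = ~np.isin(geno.codes, (0.0, 1.0, 2.0))
            if frac.any():
                het[frac] = np.broadcast_to(2.0 * p * q, het.shape)[frac]
            if coding == "hybrid":
                self.Vc = het - 2.0 * p * q
                self.wd = 4.0 * p**2 * q**2
            elif coding == "dominance_deviation":
                self.Vc = np.where(
                    geno.codes == 1.0,
                    2.0 * p * q,
                    np.where(geno.codes >= 1.0, -2.0 * q**2, -2.0 * p**2),
                )
                self.Vc[frac] = 0.0
                self.wd = (2.0 * p * q) ** 2
            else:
                raise ValueError(f"unknown dominance coding {coding!r}")
            self.Kd = self.Vc @ self.Vc.T

    def whole(self, ridge: float):
        G = RelationshipMatrix(self.ids, self.Ka / self.wa.sum(), "additive", float(self.wa.sum()))
        D = None
        if self.Vc is not None:
            D = RelationshipMatrix(self.ids, self.Kd / self.wd.sum(), "dominance", float(self.wd.sum()))
            D = regularize(D, ridge)
        return regularize(G, ridge), D

    def split(self, prior_ids, ridge: float):
        cols = np.array([self.col[s] for s in prior_ids])
        Z1 = self.Zc[:, cols]
        K1 = Z1 @ Z1.T
        da1, da2 = float(self.wa[cols].sum()), float(self.wa.sum() - self.wa[cols].sum())
        G1 = regularize(RelationshipMatrix(self.ids, K1 / da1, "additive", da1), ridge)
        G2 = regularize(
            RelationshipMatrix(self.ids, (self.Ka - K1) / da2, "additive", da2), ridge
        )
        D1 = D2 = None
        if self.Vc is not None:
            V1 = self.Vc[:, cols]
            Kd1 = V1 @ V1.T
            dd1 = float(self.wd[cols].sum())
            dd2 = float(self.wd.sum() - dd1)
            D1 = regularize(
                RelationshipMatrix(self.ids, Kd1 / dd1, "dominance", dd1), ridge
            )
            D2 = regularize(
                RelationshipMatrix(self.ids, (self.Kd - Kd1) / dd2, "dominance", dd2),
                ridge,
            )
        return G1, G2, D1, D2


def _fold_models(
    geno: GenotypeMatrix,
    cache: _GrmCache,
    train_pheno: pd.DataFrame,
    pvals: pd.DataFrame | None,
    fraction: float | None,
    spec: ModelSpec,
    opts: CVOptions,
    fixed_split=None,
):
    """Train-fold matrices + variance components: (G, D, vc, tau, pv)."""
    design = build_design(train_pheno, spec)
    if fraction is None:
        G, D = cache.whole(opts.ridge)
        vc = reml_estimate(design, G, D, spec, opts.reml)
        return design, G, D, vc, None, None
    if fixed_split is not None:
        G1, G2, D1, D2 = fixed_split
    else:
        if pvals is None:
            pvals = run_ad_gwas(geno, train_pheno, covariates=opts.gwas_covariates)
        part = select_top_fraction(pvals, fraction)
        G1, G2, D1, D2 = cache.split(part.prior_ids, opts.ridge)
    pv = fit_partition_models(design, G1, D1, G2, D2, spec, opts.reml)
    Gt, Dt = build_weighted_set(G1, G2, D1, D2, pv.tau)
    vc = reml_estimate(design, Gt, Dt, spec, opts.reml)
    return design, Gt, Dt, vc, pv.tau, pv


def run_cv(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    pvals: pd.DataFrame | None,
    scenario,
    spec: ModelSpec | None = None,
    options: CVOptions | None = None,
) -> CVReport:
    """Cross-validated prediction accuracy for one prior-information scenario.

    ``pvals=None`` (the leakage-free synthetic default) recomputes the GWAS
    within each training fold; a supplied table is used as-is for every
    fold, with a logged caveat, matching the situation where the GWAS
    predates the prediction experiment.
    """
    spec = spec or ModelSpec()
    opts = options or CVOptions()
    fraction = scenario_fraction(scenario)
    if pvals is not None and fraction is not None:
        warnings.warn(
            "using externally supplied p-values for every fold; if they were "
            "derived from the full data the CV accuracy may be optimistic"
        )
    pheno = pheno[pheno["individual_id"].isin(geno.individual_ids)]
    ids = [i for i in geno.individual_ids if i in set(pheno["individual_id"])]
    folds = assign_folds(ids, k=opts.k, seed=opts.seed)

    cache = _GrmCache(geno, spec.include_dominance, opts.dominance_coding)
    fixed_split = None
    if pvals is not None and fraction is not None:
        # supplied p-values are fold-independent: build the split once
        part = select_top_fraction(pvals, fraction)
        fixed_split = cache.split(part.prior_ids, opts.ridge)

    acc, acc_lit, h2s, taus, details = [], [], [], [], []
    for fold in range(opts.k):
        valid_ids = set(folds.fold_ids(fold))
        train_pheno = pheno[~pheno["individual_id"].isin(valid_ids)]
        valid_pheno = pheno[pheno["individual_id"].isin(valid_ids)]
        design, G, D, vc, tau, pv = _fold_models(
            geno, cache, train_pheno, pvals, fraction, spec, opts, fixed_split
        )
        if not vc.converged:
            warnings.warn(f"fold {fold}: REML refit did not converge")
        gp = genetic_parameters(vc)
        sol = solve_mme(design, G, D, vc)
        adj = adjusted_phenotypes(valid_pheno, sol.b_hat, design)
        gebv = sol.u_hat
        a = prediction_accuracy(adj, gebv, gp.h2_additive, "cor_over_h")
        a_lit = prediction_accuracy(adj, gebv, gp.h2_additive, "literal_cov_over_h2")
        acc.append(a)
        acc_lit.append(a_lit)
        h2s.append(gp.h2_additive)
        taus.append(tau)
        details.append(
            {
                "fold": fold,
                "n_valid": len(valid_ids),
                "tau": tau,
                "vc": vc.as_dict(),
                "converged": vc.converged,
                "partition": None if pv is None else dataclasses.replace(
                    pv, fit_prior=None, fit_residual=None
                ),
            }
        )
    label = scenario if isinstance(scenario, str) else f"top{round(fraction * 100)}"
    report = CVReport(
        scenario=label,
        fold_accuracy=acc,
        fold_accuracy_literal=acc_lit,
        fold_h2=h2s,
        fold_tau=taus,
        method=opts.accuracy_method,
        k=opts.k,
        seed=opts.seed,
        fold_details=details,
    )
    if opts.accuracy_method == "literal_cov_over_h2":
        report.fold_accuracy, report.fold_accuracy_literal = (
            report.fold_accuracy_literal,
            report.fold_accuracy,
        )
    return report


def compare_scenarios(reports: list) -> dict:
    """One-way ANOVA of fold-level accuracy on scenario.

    Returns the ANOVA table, F statistic, p-value, and per-scenario means.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(reports) < 2:
        raise ValueError("need at least 2 scenarios to compare")
    frames = [r.to_frame() for r in reports]
    long = pd.concat(frames, ignore_index=True).dropna(subset=["accuracy"])
    counts = long.groupby("scenario")["accuracy"].count()
    if (counts < 2).any():
        raise ValueError("every scenario needs at least 2 fold accuracies")
    model = smf.ols("accuracy ~ C(scenario)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=1)
    return {
        "anova": table,
        "F": float(table.loc["C(scenario)", "F"]),
        "p_value": float(table.loc["C(scenario)", "PR(>F)"]),
        "group_means": long.groupby("scenario")["accuracy"].mean(),
    }


def plot_accuracy(reports: list, path) -> None:
    """Bar chart of mean cross-validated accuracy per scenario (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [r.scenario for r in reports]
    means = [r.mean_accuracy for r in reports]
    sds = [r.sd_accuracy for r in reports]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(labels, means, yerr=sds, capsize=3, color="#4878a8")
    ax.set_ylabel("prediction accuracy")
    ax.set_xlabel("prior marker information")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
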