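"""End-to-end runs: config, staging, artifacts, manifest.

A run either simulates a dataset (``simulation`` block) or loads user files
(``inputs`` block), applies QC, obtains per-SNP p-values (supplied or from
the built-in scan), and then for each prior-information scenario fits the
GBLUP-GA chain on the full data (the components table) and cross-validates
prediction accuracy.  Every artifact lands under ``out_dir`` and is hashed
into ``manifest.json``; all randomness descends from the single config seed,
so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cv import CVOptions, compare_scenarios, plot_accuracy, run_cv, scenario_fraction
from .genotypes import qc_filter, read_genotypes, write_genotypes
from .grm import (
    build_additive_grm,
    build_dominance_grm,
    regularize,
    write_relationship_matrix,
)
from .mixed_model import (
    ModelSpec,
    RemlOptions,
    build_design,
    genetic_parameters,
    reml_estimate,
)
from .partition import (
    read_pvalues,
    run_ad_gwas,
    select_top_fraction,
    write_partition,
    write_pvalues,
)
from .simulate import (
    TRAIT_REGIMES,
    SimulationConfig,
    read_phenotypes,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_trait,
    write_phenotypes,
)
from .weighting import build_weighted_set, fit_partition_models

__all__ = ["RunConfig", "Pipeline", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("gblupga")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "gblupga_run",
    "genotype_format": "plink-bed",
    "simulation": {
        "n_individuals": 400,
        "n_snps": 2000,
        "n_qtl": 100,
        "maf_range": [0.05, 0.5],
        "records_per_individual": [2, 5],
        "regime": "CY",  # key into TRAIT_REGIMES, or give explicit variances
        "variances": None,  # [sigma_a2, sigma_d2, sigma_p2, sigma_e2]
        "qtl_in_top_fraction": None,  # plant QTLs in the top-x prior set
    },
    "inputs": None,  # {"genotypes":..., "format":..., "phenotypes":..., "pvalues":...}
    "qc": {"maf_min": 0.01, "snp_callrate_min": 0.90, "ind_callrate_min": 0.90},
    "model": {
        "trait": "trait",
        "fixed_factors": ["flock", "sex", "age", "year"],
        "include_dominance": True,
        "include_permanent_env": True,
    },
    "scenarios": ["none", "top5", "top10", "top15", "top20"],
    "reml": {"tol": 1e-6, "max_iter": 200},
    "cv": {"k": 5, "ridge": 1e-6, "accuracy_method": "cor_over_h"},
    "plot": False,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclasses.dataclass
class RunConfig:
    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls(raw=_merge(DEFAULT_CONFIG, user))

    @classmethod
    def default(cls, **overrides) -> "RunConfig":
        return cls(raw=_merge(DEFAULT_CONFIG, overrides))

    def __post_init__(self) -> None:
        has_inputs = self.raw.get("inputs") is not None
        has_sim = self.raw.get("simulation") is not None
        if has_inputs == has_sim:
            raise ValueError(
                "exactly one of the 'inputs' and 'simulation' blocks must be set"
            )
        for s in self.raw["scenarios"]:
            scenario_fraction(s)  # validates

    def __getitem__(self, key):
        return self.raw[key]

    def dump(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    """Stage runner; stages cache in memory and persist under out_dir."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self._cache: dict = {}
        if not log.handlers:
            logging.basicConfig(level=logging.INFO, format="%(message)s")
        fh = logging.FileHandler(self.out / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(fh)

    def _timed(self, name):
        class _T:
            def __enter__(s):
                s.t0 = time.time()
                log.info("stage %s: start", name)
                return s

            def __exit__(s, *exc):
                log.info("stage %s: done in %.1fs", name, time.time() - s.t0)

        return _T()

    # -- data ---------------------------------------------------------------

    def data(self):
        if "data" in self._cache:
            return self._cache["data"]
        cfg = self.cfg
        with self._timed("data"):
            if cfg["inputs"]:
                inp = cfg["inputs"]
                geno = read_genotypes(
                    inp["genotypes"], inp.get("format", cfg["genotype_format"])
                )
                pheno = read_phenotypes(inp["phenotypes"])
                truth = None
            else:
                sim = cfg["simulation"]
                scfg = SimulationConfig(
                    n_individuals=sim["n_individuals"],
                    n_snps=sim["n_snps"],
                    n_qtl=sim["n_qtl"],
                    maf_range=tuple(sim["maf_range"]),
                    records_per_individual=tuple(sim["records_per_individual"]),
                    seed=cfg["seed"],
                )
                variances = sim.get("variances") or TRAIT_REGIMES[sim["regime"]]
                geno = simulate_genotypes(scfg)
                qtl_indices = None
                top = sim.get("qtl_in_top_fraction")
                if top:
                    n_top = int(np.floor(top * scfg.n_snps))
                    rng = np.random.default_rng(cfg["seed"] + 7)
                    qtl_indices = rng.choice(n_top, size=scfg.n_qtl, replace=False)
                arch = simulate_trait(
                    geno,
                    scfg.n_qtl,
                    *variances,
                    seed=cfg["seed"],
                    qtl_indices=qtl_indices,
                )
                pheno = simulate_phenotypes(
                    geno, arch, scfg, trait=cfg["model"]["trait"]
                )
                truth = arch
                write_genotypes(
                    geno, self.out / "genotypes", cfg["genotype_format"]
                )
                write_phenotypes(pheno, self.out / "phenotypes.csv")
                truth.to_frame().to_csv(self.out / "truth_qtl.csv", index=False)
                pd.DataFrame(
                    {
                        "individual_id": geno.individual_ids,
                        "true_bv": arch.true_breeding_values,
                        "true_dv": arch.true_dominance_values,
                    }
                ).to_csv(self.out / "truth_individuals.csv", index=False)
            self._cache["data"] = (geno, pheno, truth)
        return self._cache["data"]

    def qc(self):
        if "qc" in self._cache:
            return self._cache["qc"]
        geno, pheno, truth = self.data()
        with self._timed("qc"):
            q = self.cfg["qc"]
            geno_qc, report = qc_filter(
                geno, q["maf_min"], q["snp_callrate_min"], q["ind_callrate_min"]
            )
            report.to_frame().to_csv(self.out / "qc_report.csv", index=False)
            log.info(
                "qc: %d -> %d SNPs, %d individuals removed",
                report.n_snps_in,
                report.n_snps_out,
                report.n_individuals_removed,
            )
            self._cache["qc"] = geno_qc
        return geno_qc

    def gwas(self):
        if "pvals" in self._cache:
            return self._cache["pvals"]
        cfg = self.cfg
        geno = self.qc()
        with self._timed("gwas"):
            if cfg["inputs"] and cfg["inputs"].get("pvalues"):
                pvals = read_pvalues(cfg["inputs"]["pvalues"])
            else:
                _, pheno, _ = self.data()
                pvals = run_ad_gwas(
                    geno, pheno, covariates=tuple(cfg["model"]["fixed_factors"])
                )
                write_pvalues(pvals, self.out / "pvalues.tsv")
            self._cache["pvals"] = pvals
        return pvals

    def partition(self, fraction: float):
        pvals = self.gwas()
        part = select_top_fraction(pvals, fraction)
        write_partition(part, self.out / "partitions" / f"top{round(fraction*100)}")
        return part

    def grm(self):
        """Whole-panel G (and D when modelled), written to CSV."""
        geno = self.qc()
        with self._timed("grm"):
            G = build_additive_grm(geno)
            write_relationship_matrix(G, self.out / "G.csv")
            D = None
            if self.cfg["model"]["include_dominance"]:
                D = build_dominance_grm(geno)
                write_relationship_matrix(D, self.out / "D.csv")
        return G, D

    # -- model fitting ------------------------------------------------------

    def _model_spec(self) -> ModelSpec:
        m = self.cfg["model"]
        return ModelSpec(
            trait=m["trait"],
            fixed_factors=tuple(m["fixed_factors"]),
            include_dominance=m["include_dominance"],
            include_permanent_env=m["include_permanent_env"],
        )

    def _reml_options(self) -> RemlOptions:
        r = self.cfg["reml"]
        return RemlOptions(tol=r["tol"], max_iter=r["max_iter"])

    def fit(self):
        """Plain whole-panel GBLUP variance components (the 'G' rows)."""
        geno = self.qc()
        _, pheno, _ = self.data()
        spec = self._model_spec()
        ridge = self.cfg["cv"]["ridge"]
        with self._timed("fit"):
            design = build_design(pheno, spec)
            G = regularize(build_additive_grm(geno), ridge)
            D = (
                regularize(build_dominance_grm(geno), ridge)
                if spec.include_dominance
                else None
            )
            vc = reml_estimate(design, G, D, spec, self._reml_options())
            self._cache["fit_none"] = (design, G, D, vc)
        return vc

    def ga(self) -> pd.DataFrame:
        """Per-scenario partition fits, tau, and weighted-matrix refits.

        Produces a components table shaped like the published ones: rows
        G1, G2, Gt per prior fraction with variance components, genetic
        parameters, and tau.
        """
        geno = self.qc()
        _, pheno, _ = self.data()
        pvals = self.gwas()
        spec = self._model_spec()
        ropts = self._reml_options()
        ridge = self.cfg["cv"]["ridge"]
        rows = []

        def row(label, matrix, vc, tau=None):
            gp = genetic_parameters(vc)
            return {
                "prior_fraction": label,
                "matrix": matrix,
                "sigma_a2": vc.sigma_a2,
                "sigma_d2": vc.sigma_d2 if spec.include_dominance else np.nan,
                "sigma_p2": vc.sigma_p2,
                "sigma_e2": vc.sigma_e2,
                "h2_additive": gp.h2_additive,
                "h2_dominance": gp.h2_dominance if spec.include_dominance else np.nan,
                "repeatability": gp.repeatability,
                "tau": tau,
                "converged": vc.converged,
            }

        with self._timed("ga"):
            design = build_design(pheno, spec)
            for scenario in self.cfg["scenarios"]:
                fraction = scenario_fraction(scenario)
                if fraction is None:
                    vc = self.fit()
                    rows.append(row("none", "G", vc))
                    continue
                part = self.partition(fraction)
                G1 = regularize(build_additive_grm(geno, part.prior_ids), ridge)
                G2 = regularize(build_additive_grm(geno, part.residual_ids), ridge)
                D1 = D2 = None
                if spec.include_dominance:
                    D1 = regularize(build_dominance_grm(geno, part.prior_ids), ridge)
                    D2 = regularize(build_dominance_grm(geno, part.residual_ids), ridge)
                pv = fit_partition_models(design, G1, D1, G2, D2, spec, ropts)
                Gt, Dt = build_weighted_set(G1, G2, D1, D2, pv.tau)
                vct = reml_estimate(design, Gt, Dt, spec, ropts)
                label = scenario if isinstance(scenario, str) else f"top{round(fraction*100)}"
                rows.append(row(label, "G1", pv.fit_prior, pv.tau))
                rows.append(row(label, "G2", pv.fit_residual, 1.0 - pv.tau))
                rows.append(row(label, "Gt", vct))
                log.info("scenario %s: tau=%.3f", label, pv.tau)
            table = pd.DataFrame(rows)
            table.to_csv(self.out / "components.csv", index=False)
        return table

    # -- cross-validation ---------------------------------------------------

    def cv(self) -> list:
        geno = self.qc()
        _, pheno, _ = self.data()
        cfg = self.cfg
        pvals = None
        if cfg["inputs"] and cfg["inputs"].get("pvalues"):
            pvals = self.gwas()
        spec = self._model_spec()
        opts = CVOptions(
            k=cfg["cv"]["k"],
            seed=cfg["seed"],
            ridge=cfg["cv"]["ridge"],
            accuracy_method=cfg["cv"]["accuracy_method"],
            reml=self._reml_options(),
            gwas_covariates=tuple(cfg["model"]["fixed_factors"]),
        )
        reports = []
        with self._timed("cv"):
            for scenario in cfg["scenarios"]:
                rep = run_cv(geno, pheno, pvals, scenario, spec, opts)
                log.info(
                    "cv %s: mean accuracy %.4f (sd %.4f)",
                    rep.scenario,
                    rep.mean_accuracy,
                    rep.sd_accuracy,
                )
                reports.append(rep)
            pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
                self.out / "cv_report.csv", index=False
            )
        self._cache["cv"] = reports
        return reports

    def report(self) -> dict:
        reports = self._cache.get("cv") or self.cv()
        summary = {
            r.scenario: {
                "mean_accuracy": r.mean_accuracy,
                "sd_accuracy": r.sd_accuracy,
                "mean_h2": float(np.nanmean(r.fold_h2)),
                "taus": [t for t in r.fold_tau if t is not None],
            }
            for r in reports
        }
        out = {"scenarios": summary}
        if len(reports) >= 2:
            cmp_res = compare_scenarios(reports)
            out["anova_F"] = cmp_res["F"]
            out["anova_p"] = cmp_res["p_value"]
        (self.out / "cv_summary.json").write_text(json.dumps(out, indent=1))
        if self.cfg["plot"]:
            plot_accuracy(reports, self.out / "accuracy.png")
        return out

    def manifest(self) -> dict:
        files = sorted(
            p for p in self.out.rglob("*") if p.is_file() and p.name != "run.log"
        )
        man = {
            "gblupga_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": self.cfg["seed"],
            "files": {str(p.relative_to(self.out)): _sha256(p) for p in files},
        }
        (self.out / "manifest.json").write_text(json.dumps(man, indent=1))
        return man

    def all(self) -> dict:
        self.data()
        self.qc()
        self.gwas()
        self.ga()
        self.cv()
        out = self.report()
        self.manifest()
        return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the accuracy summary."""
    return Pipeline(config).all()
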