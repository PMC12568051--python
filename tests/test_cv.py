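"""Cross-validation: folds, adjusted phenotypes, accuracy, hygiene, ANOVA."""

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest

from gblupga.cv import (
    CVOptions,
    CVReport,
    adjusted_phenotypes,
    assign_folds,
    compare_scenarios,
    prediction_accuracy,
    run_cv,
    scenario_fraction,
)
from gblupga.mixed_model import ModelSpec, RemlOptions, build_design


class TestAssignFolds:
    def test_balanced_partition(self):
        ids = [f"i{k}" for k in range(10)]
        fa = assign_folds(ids, k=5, seed=0)
        sizes = [len(fa.fold_ids(f)) for f in range(5)]
        assert sizes == [2] * 5
        assert set().union(*(fa.fold_ids(f) for f in range(5))) == set(ids)

    def test_deterministic_per_seed(self):
        ids = [f"i{k}" for k in range(23)]
        assert assign_folds(ids, 5, 3).assignment == assign_folds(ids, 5, 3).assignment
        assert assign_folds(ids, 5, 3).assignment != assign_folds(ids, 5, 4).assignment

    def test_sizes_differ_at_most_one(self):
        fa = assign_folds([f"i{k}" for k in range(23)], 5, 1)
        sizes = sorted(len(fa.fold_ids(f)) for f in range(5))
        assert sizes[-1] - sizes[0] <= 1

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            assign_folds(["a", "b"], k=5)


class TestAdjustedPhenotypes:
    def _design(self, ph):
        spec = ModelSpec(fixed_factors=("flock", "sex"))
        return build_design(ph, spec)

    def test_zero_effects_give_raw_means(self):
        ph = pd.DataFrame(
            {
                "individual_id": ["a", "a", "b"],
                "value": [1.0, 3.0, 5.0],
                "flock": ["x", "y", "x"],
                "sex": ["m", "m", "f"],
            }
        )
        d = self._design(ph)
        b0 = pd.Series(0.0, index=d.x_columns)
        adj = adjusted_phenotypes(ph, b0, d)
        assert adj["a"] == pytest.approx(2.0)
        assert adj["b"] == pytest.approx(5.0)

    def test_two_factor_hand_computation(self):
        ph = pd.DataFrame(
            {
                "individual_id": ["a", "a", "b", "b"],
                "value": [10.0, 12.0, 20.0, 22.0],
                "flock": ["x", "y", "x", "y"],
                "sex": ["m", "m", "f", "f"],
            }
        )
        d = self._design(ph)
        b = pd.Series(
            {"intercept": 1.0, "flock=y": 2.0, "sex=m": 3.0}, index=d.x_columns
        ).fillna(0.0)
        adj = adjusted_phenotypes(ph, b, d)
        # a: (10-1-3) + (12-1-2-3) -> mean 6.0 ; b: (20-1) + (22-1-2) -> 19.0
        assert adj["a"] == pytest.approx(6.0)
        assert adj["b"] == pytest.approx(19.0)

    def test_unseen_level_dropped_with_warning(self):
        train = pd.DataFrame(
            {
                "individual_id": ["a", "b"],
                "value": [1.0, 2.0],
                "flock": ["x", "y"],
                "sex": ["m", "f"],
            }
        )
        d = self._design(train)
        b0 = pd.Series(0.0, index=d.x_columns)
        valid = pd.DataFrame(
            {
                "individual_id": ["c", "c"],
                "value": [4.0, 6.0],
                "flock": ["x", "z"],  # z unseen
                "sex": ["m", "m"],
            }
        )
        with pytest.warns(UserWarning, match="unseen"):
            adj = adjusted_phenotypes(valid, b0, d)
        assert adj["c"] == pytest.approx(4.0)  # only the seen-level record


class TestPredictionAccuracy:
    def test_perfect_prediction_unit_h2(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert prediction_accuracy(v, v, 1.0) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        idx = [f"i{k}" for k in range(2000)]
        a = pd.Series(rng.normal(size=2000), index=idx)
        g = pd.Series(rng.normal(size=2000), index=idx)
        assert abs(prediction_accuracy(a, g, 0.25)) < 0.12

    def test_known_noise_ratio_closed_form(self):
        """gebv = bv + noise: accuracy = sqrt(var_bv/(var_bv+var_n))/sqrt(h2)."""
        rng = np.random.default_rng(1)
        n = 4000
        bv = rng.normal(0, 2.0, n)
        idx = [f"i{k}" for k in range(n)]
        gebv = pd.Series(bv + rng.normal(0, 1.0, n), index=idx)
        adj = pd.Series(bv, index=idx)
        expected = np.sqrt(4.0 / 5.0) / np.sqrt(0.25)
        got = prediction_accuracy(adj, gebv, 0.25)
        assert got == pytest.approx(expected, rel=0.03)

    def test_literal_method_is_cov_over_h2(self):
        rng = np.random.default_rng(2)
        idx = [f"i{k}" for k in range(50)]
        a = pd.Series(rng.normal(size=50), index=idx)
        g = pd.Series(rng.normal(size=50), index=idx)
        lit = prediction_accuracy(a, g, 0.3, "literal_cov_over_h2")
        assert lit == pytest.approx(np.cov(a, g, ddof=1)[0, 1] / 0.3)

    def test_zero_variance_is_missing(self):
        idx = list("abc")
        a = pd.Series([1.0, 1.0, 1.0], index=idx)
        g = pd.Series([1.0, 2.0, 3.0], index=idx)
        assert np.isnan(prediction_accuracy(a, g, 0.5))

    def test_scenario_labels(self):
        assert scenario_fraction("none") is None
        assert scenario_fraction("top15") == 0.15
        assert scenario_fraction(0.07) == 0.07
        with pytest.raises(ValueError):
            scenario_fraction("top99")


@pytest.fixture(scope="module")
def cv_world():
    """Small enriched dataset for CV behaviour tests."""
    from gblupga.simulate import (
        SimulationConfig,
        simulate_genotypes,
        simulate_phenotypes,
        simulate_trait,
    )

    cfg = SimulationConfig(n_individuals=200, n_snps=500, n_qtl=15, seed=30)
    geno = simulate_genotypes(cfg)
    arch = simulate_trait(
        geno, 15, sigma_a2=10.0, sigma_d2=2.0, sigma_p2=0.5, sigma_e2=20.0, seed=30
    )
    pheno = simulate_phenotypes(geno, arch, cfg)
    return geno, arch, pheno


class TestRunCV:
    def test_none_scenario_bypasses_tau(self, cv_world):
        geno, _, pheno = cv_world
        rep = run_cv(geno, pheno, None, "none", ModelSpec(), CVOptions(k=3, seed=0))
        assert rep.scenario == "none"
        assert all(t is None for t in rep.fold_tau)
        assert len(rep.fold_accuracy) == 3
        assert rep.mean_accuracy == pytest.approx(np.nanmean(rep.fold_accuracy))

    def test_accuracy_within_theoretical_range(self, cv_world):
        geno, _, pheno = cv_world
        rep = run_cv(geno, pheno, None, "none", ModelSpec(), CVOptions(k=3, seed=0))
        for a, h2 in zip(rep.fold_accuracy, rep.fold_h2):
            assert abs(a) <= 1.0 / np.sqrt(h2) + 1e-9

    def test_validation_phenotypes_cannot_leak(self, cv_world):
        """Perturbing validation records leaves tau and the training fit of
        that fold bit-identical (training/validation hygiene)."""
        geno, _, pheno = cv_world
        opts = CVOptions(k=3, seed=1, reml=RemlOptions(tol=1e-6))
        rep_a = run_cv(geno, pheno, None, "top10", ModelSpec(), opts)

        from gblupga.cv import assign_folds as _af

        ids = [i for i in geno.individual_ids if i in set(pheno["individual_id"])]
        fold0 = set(_af(ids, 3, 1).fold_ids(0))
        pert = pheno.copy()
        mask = pert["individual_id"].isin(fold0)
        pert.loc[mask, "value"] += 1000.0
        rep_b = run_cv(geno, pert, None, "top10", ModelSpec(), opts)
        assert rep_a.fold_tau[0] == rep_b.fold_tau[0]
        assert rep_a.fold_details[0]["vc"] == rep_b.fold_details[0]["vc"]
        assert rep_a.fold_h2[0] == rep_b.fold_h2[0]


class TestCompareScenarios:
    def _report(self, label, accs):
        k = len(accs)
        return CVReport(
            scenario=label,
            fold_accuracy=list(accs),
            fold_accuracy_literal=list(accs),
            fold_h2=[0.3] * k,
            fold_tau=[None] * k,
            method="cor_over_h",
            k=k,
            seed=0,
        )

    def test_identical_groups_give_f_zero(self):
        accs = [0.5, 0.6, 0.7, 0.55, 0.65]
        out = compare_scenarios([self._report("none", accs), self._report("top5", accs)])
        assert out["F"] == pytest.approx(0.0, abs=1e-10)
        assert out["p_value"] == pytest.approx(1.0, abs=1e-10)

    def test_planted_shift_is_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.5, 0.01, 5)
        out = compare_scenarios(
            [self._report("none", base), self._report("top5", base + 0.1)]
        )
        assert out["p_value"] < 0.001

    def test_f_matches_hand_sums_of_squares(self):
        a = [0.50, 0.60, 0.55, 0.45, 0.65]
        b = [0.70, 0.80, 0.75, 0.65, 0.85]
        out = compare_scenarios([self._report("none", a), self._report("top5", b)])
        all_ = np.array(a + b)
        ssb = 5 * ((np.mean(a) - all_.mean()) ** 2 + (np.mean(b) - all_.mean()) ** 2)
        ssw = sum((np.array(a) - np.mean(a)) ** 2) + sum((np.array(b) - np.mean(b)) ** 2)
        f_hand = (ssb / 1) / (ssw / 8)
        assert out["F"] == pytest.approx(f_hand, rel=1e-10)

    def test_requires_two_scenarios(self):
        with pytest.raises(ValueError):
            compare_scenarios([self._report("none", [0.5, 0.6])])
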