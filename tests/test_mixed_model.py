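"""Animal-model machinery: design, MME vs direct BLUP oracle, REML, ratios."""

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gblupga.grm import RelationshipMatrix
from gblupga.mixed_model import (
    ModelSpec,
    RemlOptions,
    VarianceComponents,
    build_design,
    genetic_parameters,
    reml_estimate,
    solve_mme,
)

SIMPLE = ModelSpec(
    fixed_factors=("flock",), include_dominance=False, include_permanent_env=False
)


def _toy_pheno(rng, n_ind, records=1, factors=("flock",)):
    rows = []
    for i in range(n_ind):
        for _ in range(records):
            rows.append(
                {
                    "individual_id": f"i{i}",
                    "value": rng.normal(),
                    **{f: f"{f}{rng.integers(0, 2)}" for f in factors},
                }
            )
    return pd.DataFrame(rows)


def _random_grm(rng, n):
    ids = [f"i{i}" for i in range(n)]
    L = rng.normal(size=(n, n + 4)) / np.sqrt(n + 4)
    return RelationshipMatrix(ids, L @ L.T + 0.4 * np.eye(n), "additive", 1.0)


class TestBuildDesign:
    def test_single_level_factor_gives_intercept_only(self):
        ph = pd.DataFrame(
            {"individual_id": ["a", "b"], "value": [1.0, 2.0], "flock": ["f", "f"]}
        )
        d = build_design(ph, SIMPLE)
        assert d.x_columns == ["intercept"]
        npt.assert_array_equal(d.X, [[1.0], [1.0]])

    def test_incidence_counts_records(self):
        ph = pd.DataFrame(
            {
                "individual_id": ["a", "a", "a", "b"],
                "value": [1.0, 2.0, 3.0, 4.0],
                "flock": ["x", "x", "y", "y"],
            }
        )
        d = build_design(ph, SIMPLE)
        Z = d.Zu
        assert Z[:, 0].sum() == 3 and Z[:, 1].sum() == 1
        # hand-counted tallies
        npt.assert_array_equal(d.X.T @ d.X, [[4.0, 2.0], [2.0, 2.0]])
        npt.assert_array_equal(Z.T @ Z, [[3.0, 0.0], [0.0, 1.0]])

    def test_individual_order_must_cover(self):
        ph = pd.DataFrame({"individual_id": ["a", "b"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="individual_order"):
            build_design(ph, SIMPLE, individual_order=["a"])


class TestSolveMME:
    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        ph = _toy_pheno(rng, 6)
        d = build_design(ph, SIMPLE)
        G = _random_grm(rng, 6)
        sol = solve_mme(d, G, None, VarianceComponents(1e-10, 0, 0, 1.0))
        npt.assert_allclose(sol.u_hat.to_numpy(), 0.0, atol=1e-6)

    def test_duplicated_records_leave_fixed_effects_unchanged_without_shrinkage(self):
        """Balanced replication leaves b_hat unchanged in the OLS limit.

        (With a genuinely random u the invariance does not hold: doubling
        every record doubles the data's weight against the G^-1 penalty and
        shifts the shrinkage, hence b_hat; verified against the GLS oracle.)
        """
        rng = np.random.default_rng(1)
        ph = _toy_pheno(rng, 8)
        G = _random_grm(rng, 8)
        vc = VarianceComponents(1e-9, 0, 0, 2.0)
        d1 = build_design(ph, SIMPLE)
        d2 = build_design(pd.concat([ph, ph], ignore_index=True), SIMPLE)
        b1 = solve_mme(d1, G, None, vc).b_hat
        b2 = solve_mme(d2, G, None, vc).b_hat
        npt.assert_allclose(b1.to_numpy(), b2.to_numpy(), atol=1e-7)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=5, max_value=10),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_gls_blup_oracle(self, n, seed):
        """u_hat equals sigma_a2 G Z'(Z G Z' sigma_a2 + I sigma_e2)^-1 (y-Xb),
        with b from generalized least squares, on random small toys."""
        rng = np.random.default_rng(seed)
        ph = _toy_pheno(rng, n)
        d = build_design(ph, SIMPLE)
        G = _random_grm(rng, n)
        sa2, se2 = 1.7, 0.9
        sol = solve_mme(d, G, None, VarianceComponents(sa2, 0, 0, se2))
        y, X, Z = d.y, d.X, d.Zu
        Gm = G.align(d.individual_ids)
        V = sa2 * Z @ Gm @ Z.T + se2 * np.eye(len(y))
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = sa2 * Gm @ Z.T @ Vi @ (y - X @ b)
        npt.assert_allclose(sol.b_hat.to_numpy(), b, atol=1e-8)
        npt.assert_allclose(sol.u_hat.to_numpy(), u, atol=1e-8)

    def test_unphenotyped_individuals_predicted_through_g(self):
        rng = np.random.default_rng(5)
        ph = _toy_pheno(rng, 6, records=2)
        d = build_design(ph, SIMPLE)
        G = _random_grm(rng, 9)  # i0..i8; i6..i8 have no records
        sol = solve_mme(d, G, None, VarianceComponents(1.0, 0, 0, 1.0))
        assert list(sol.u_hat.index) == G.individual_ids
        assert np.isfinite(sol.u_hat.loc["i8"])


class TestReml:
    def test_grid_search_oracle(self):
        """Optimum matches a brute-force restricted-likelihood grid search."""
        rng = np.random.default_rng(7)
        n = 12
        G = _random_grm(rng, n)
        Gm = G.values
        L = np.linalg.cholesky(Gm)
        u = L @ rng.normal(size=n) * np.sqrt(2.0)
        ph = pd.DataFrame(
            {
                "individual_id": [f"i{i}" for i in range(n)],
                "value": 1.0 + u + rng.normal(0, 1, n),
            }
        )
        d = build_design(ph, SIMPLE)
        vc = reml_estimate(d, G, None, SIMPLE, RemlOptions(tol=1e-10))

        def rll(sa2, se2):
            V = sa2 * Gm + se2 * np.eye(n)
            Vi = np.linalg.inv(V)
            X = d.X
            XtViX = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
            return -0.5 * (
                np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtViX)[1]
                + d.y @ P @ d.y
            )

        grid = np.linspace(0.05, 8.0, 160)
        best = max(((rll(a, e), a, e) for a in grid for e in grid))
        assert vc.loglik >= best[0] - 1e-6
        assert vc.sigma_a2 == pytest.approx(best[1], abs=0.1)
        assert vc.sigma_e2 == pytest.approx(best[2], abs=0.1)

    def test_null_data_pins_genetic_variances(self, small_panel):
        from gblupga.grm import build_additive_grm, build_dominance_grm, regularize

        rng = np.random.default_rng(13)
        ids = small_panel.individual_ids[:150]
        ph = pd.DataFrame(
            {"individual_id": np.repeat(ids, 2), "value": rng.normal(0, 1, 300)}
        )
        spec = ModelSpec(fixed_factors=(), include_permanent_env=True)
        d = build_design(ph, spec)
        G = regularize(build_additive_grm(small_panel.subset(individuals=ids)), 1e-6)
        D = regularize(build_dominance_grm(small_panel.subset(individuals=ids)), 1e-6)
        vc = reml_estimate(d, G, D, spec, RemlOptions(tol=1e-8))
        assert vc.sigma_a2 <= vc.floor * 10
        assert vc.sigma_d2 <= vc.floor * 10
        # residual-only restricted likelihood (same constant convention)
        y, X = d.y, d.X
        n, p = len(y), X.shape[1]
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = resid @ resid / (n - p)
        ll0 = -0.5 * (
            (n - p) * np.log(s2) + np.linalg.slogdet(X.T @ X)[1] + (n - p)
        )
        assert abs(vc.loglik - ll0) < 0.5

    def test_loglik_never_decreases(self, cy_dataset):
        geno, _, pheno = cy_dataset
        from gblupga.grm import build_additive_grm, build_dominance_grm, regularize

        spec = ModelSpec()
        d = build_design(pheno, spec)
        G = regularize(build_additive_grm(geno), 1e-6)
        D = regularize(build_dominance_grm(geno), 1e-6)
        vc1 = reml_estimate(d, G, D, spec, RemlOptions(max_iter=1))
        vc = reml_estimate(d, G, D, spec, RemlOptions(tol=1e-8))
        assert vc.loglik >= vc1.loglik - 1e-8
        assert vc.converged


class TestGeneticParameters:
    @pytest.mark.parametrize(
        "comps,expected",
        [
            # published CY weighted-matrix fit
            ((9672.55, 2049.59, 4.40e-7, 26699.68), (0.252, 0.053, 0.305)),
            # published BW top-15% weighted-matrix fit
            ((9.90, 6.31e-7, 2.85, 17.22), (0.330, 0.000, 0.425)),
            ((1.0, 0.0, 0.0, 3.0), (0.25, 0.0, 0.25)),
        ],
    )
    def test_worked_examples(self, comps, expected):
        gp = genetic_parameters(VarianceComponents(*comps))
        assert round(gp.h2_additive, 3) == expected[0]
        assert round(gp.h2_dominance, 3) == expected[1]
        assert round(gp.repeatability, 3) == expected[2]

    def test_scale_invariance(self):
        a = genetic_parameters(VarianceComponents(2.0, 1.0, 0.5, 4.0))
        b = genetic_parameters(VarianceComponents(20.0, 10.0, 5.0, 40.0))
        assert a == b

    def test_ordering_invariant(self):
        gp = genetic_parameters(VarianceComponents(2.0, 1.0, 0.5, 4.0))
        assert gp.h2_additive + gp.h2_dominance <= gp.repeatability + 1e-12 <= 1.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            genetic_parameters(VarianceComponents(0.0, 0.0, 0.0, 0.0))
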