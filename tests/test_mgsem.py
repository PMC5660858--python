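import numpy as np
import pytest

import miequiv as mq
from miequiv.mgsem import (
    CONSTRAINT_SETS,
    ConstraintSet,
    ParamSet,
    chisq_diff,
    cov_equality_test,
    dof,
    fit,
    implied_moments,
    ml_discrepancy,
    run_sequence,
)
from miequiv.model_io import GroupMoments

from conftest import random_paramset


class TestImpliedMoments:
    def test_null_loadings(self):
        ps = ParamSet([np.array([1.0, -2.0])], [np.zeros((2, 1))],
                      [np.eye(1)], [np.array([0.5, 0.7])], [np.zeros(1)])
        mu, sigma = implied_moments(ps, 0)
        np.testing.assert_allclose(mu, [1.0, -2.0])
        np.testing.assert_allclose(sigma, np.diag([0.5, 0.7]))

    def test_hand_computation(self):
        ps = ParamSet([np.zeros(2)], [np.ones((2, 1))], [np.eye(1)],
                      [np.ones(2)], [np.zeros(1)])
        mu, sigma = implied_moments(ps, 0)
        np.testing.assert_allclose(mu, [0.0, 0.0])
        np.testing.assert_allclose(sigma, [[2.0, 1.0], [1.0, 2.0]])

    def test_matrix_product_oracle(self, rng, simple_model):
        ps = random_paramset(rng, simple_model, 2, tau_nonzero=True)
        for j in range(2):
            mu, sigma = implied_moments(ps, j)
            mu2 = ps.gamma[j] + np.einsum("pk,k->p", ps.lam[j], ps.tau[j])
            s2 = np.einsum("pk,kl,ql->pq", ps.lam[j], ps.phi[j], ps.lam[j]) \
                + np.diag(ps.psi[j])
            np.testing.assert_allclose(mu, mu2, atol=1e-12)
            np.testing.assert_allclose(sigma, s2, atol=1e-12)


class TestMlDiscrepancy:
    def test_saturated_parameters_zero(self, rng, simple_model):
        ps = random_paramset(rng, simple_model, 2)
        data = []
        for j in range(2):
            mu, sigma = implied_moments(ps, j)
            data.append(GroupMoments(f"g{j}", 100, mu, sigma))
        assert ml_discrepancy(ps, data) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_closed_form(self):
        # p=1: s2=2, sigma2=1, equal means -> F = 1 - log 2
        ps = ParamSet([np.zeros(1)], [np.ones((1, 1))],
                      [np.array([[0.5]])], [np.array([0.5])], [np.zeros(1)])
        data = [GroupMoments("g", 50, np.zeros(1), np.array([[2.0]]))]
        assert ml_discrepancy(ps, data) == pytest.approx(1.0 - np.log(2.0))

    def test_likelihood_ratio_oracle(self, rng, simple_model):
        # independently coded via eigendecompositions
        ps = random_paramset(rng, simple_model, 2, tau_nonzero=True)
        data = []
        for j in range(2):
            a = rng.standard_normal((60, 6))
            cov = (a - a.mean(0)).T @ (a - a.mean(0)) / 60
            data.append(GroupMoments(f"g{j}", 60, a.mean(0), cov))
        N = sum(g.n for g in data)
        expected = 0.0
        for j, gm in enumerate(data):
            mu, sigma = implied_moments(ps, j)
            w, V = np.linalg.eigh(sigma)
            siginv = V @ np.diag(1.0 / w) @ V.T
            d = gm.mean - mu
            f = (np.sum(np.log(w)) - np.sum(np.log(np.linalg.eigvalsh(gm.cov)))
                 + np.trace(gm.cov @ siginv) - 6 + d @ siginv @ d)
            expected += gm.n / N * f
        assert ml_discrepancy(ps, data) == pytest.approx(expected, abs=1e-10)


class TestDof:
    @pytest.mark.parametrize("name,expected", [
        ("configural", 12), ("metric", 15), ("residuals", 21),
        ("varfactor", 27), ("scalar", 18), ("strong.means", 21),
        ("strict.residuals", 24), ("strict.means", 27),
        ("equal.cov", 21), ("saturated", 0),
    ])
    def test_two_group_literacy_dimensions(self, literacy_model, name,
                                           expected):
        assert dof(literacy_model, name, m=2) == expected

    def test_single_group_configural(self, literacy_model):
        assert dof(literacy_model, "configural", m=1) == 6

    def test_overparameterized_rejected(self):
        model = mq.parse_model("F =~ a")
        with pytest.raises(ValueError, match="over-parameterized"):
            dof(model, "configural", m=1)

    def test_permutation_invariance(self, rng):
        base = mq.parse_model("A =~ x1 + x2 + x3\nB =~ x4 + x5\n")
        perm = mq.parse_model("B =~ x4 + x5\nA =~ x1 + x2 + x3\n")
        for name in CONSTRAINT_SETS:
            assert dof(base, name, m=3) == dof(perm, name, m=3)

    def test_p_mismatch(self, literacy_model):
        with pytest.raises(ValueError):
            dof(literacy_model, "metric", m=2, p=4)


class TestFit:
    def test_population_identity_and_recovery(self, rng, simple_model):
        ps = random_paramset(rng, simple_model, 2)
        # impose metric structure
        ps.lam[1] = ps.lam[0].copy()
        data = []
        for j, n in enumerate((200, 300)):
            mu, sigma = implied_moments(ps, j)
            data.append(GroupMoments(f"g{j}", n, mu, sigma,
                                     simple_model.all_variables))
        fr = fit(data, simple_model, "metric")
        assert fr.converged
        assert fr.fml <= 1e-8
        np.testing.assert_allclose(fr.estimates.lam[0], ps.lam[0], atol=1e-4)
        np.testing.assert_allclose(fr.estimates.psi[0], ps.psi[0], atol=1e-4)
        np.testing.assert_allclose(fr.estimates.phi[1], ps.phi[1], atol=1e-4)
        np.testing.assert_allclose(fr.estimates.gamma[0], ps.gamma[0],
                                   atol=1e-4)

    def test_configural_df_six_per_group(self, literacy_model,
                                         invariant_design):
        design = mq.default_design(literacy_model, ns=(78, 174), seed=3)
        data = mq.generate(design, "moments")
        for gm in data:
            fr = fit([gm], literacy_model, "configural")
            assert fr.df == 6

    def test_saturated_fit(self, invariant_moments, simple_model):
        fr = fit(invariant_moments, simple_model, "saturated")
        assert fr.fml == 0.0
        assert fr.df == 0

    def test_statistic_scale_option(self, invariant_moments, simple_model):
        a = fit(invariant_moments, simple_model, "metric", scale="n_minus_m")
        b = fit(invariant_moments, simple_model, "metric", scale="n")
        N = sum(g.n for g in invariant_moments)
        assert b.tml == pytest.approx(a.tml * N / (N - 2), rel=1e-6)

    def test_equality_constraints_exact(self, invariant_moments,
                                        simple_model):
        fr = fit(invariant_moments, simple_model, "strict.residuals")
        est = fr.estimates
        np.testing.assert_array_equal(est.lam[0], est.lam[1])
        np.testing.assert_array_equal(est.gamma[0], est.gamma[1])
        np.testing.assert_array_equal(est.psi[0], est.psi[1])
        np.testing.assert_array_equal(est.tau[0], np.zeros(3))

    def test_permuted_variable_order_same_statistic(self, rng):
        model = mq.parse_model("A =~ x1 + x2\nB =~ x3 + x4\n")
        design = mq.default_design(model, ns=(120, 140), seed=9)
        data = mq.generate(design, "moments")
        perm = [2, 3, 0, 1]
        model_p = mq.parse_model("B =~ x3 + x4\nA =~ x1 + x2\n")
        data_p = [
            GroupMoments(g.label, g.n, g.mean[perm],
                         g.cov[np.ix_(perm, perm)],
                         tuple(g.variables[i] for i in perm))
            for g in data
        ]
        a = fit(data, model, "metric")
        b = fit(data_p, model_p, "metric")
        assert b.tml == pytest.approx(a.tml, abs=1e-6)

    def test_heywood_warning(self, rng):
        model = mq.parse_model("A =~ x1 + x2 + x3\n")
        design = mq.default_design(model, ns=(60, 60), seed=1, psi=1e-8)
        data = mq.generate(design, "population")
        fr = fit(data, model, "configural")
        assert any("Heywood" in w for w in fr.warnings)


class TestChisqDiff:
    def test_child_equals_parent(self, invariant_moments, simple_model):
        fr = fit(invariant_moments, simple_model, "metric")
        d = chisq_diff(fr, fr)
        assert d.tdiff == 0.0
        assert d.dfdiff == 0

    def test_non_nested_rejected(self, invariant_moments, simple_model):
        child = fit(invariant_moments, simple_model, "metric")
        parent = fit(invariant_moments, simple_model, "strict.means")
        with pytest.raises(ValueError, match="not nested"):
            chisq_diff(child, parent)

    def test_printed_arithmetic(self):
        # difference = child T - parent T, df likewise
        a = mq.mgsem.FitResult("fit.scalar", 0, 23.732, 18, 0.164, None,
                               True, 0, 252, 2)
        b = mq.mgsem.FitResult("fit.metric", 0, 20.033, 15, 0.171, None,
                               True, 0, 252, 2)
        d = chisq_diff(a, b)
        assert d.tdiff == pytest.approx(3.699, abs=1e-9)
        assert d.dfdiff == 3
        assert round(d.pvalue, 3) == 0.296

    def test_refit_oracle(self, simple_model):
        # warm-started and cold-started fits give the same difference
        design = mq.default_design(simple_model, ns=(130, 150), seed=21)
        data = mq.generate(design, "moments")
        parent = fit(data, simple_model, "metric")
        warm = fit(data, simple_model, "residuals",
                   start=parent.estimates)
        cold = fit(data, simple_model, "residuals")
        d1 = chisq_diff(warm, parent).tdiff
        d2 = chisq_diff(cold, parent).tdiff
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_negative_difference_flagged(self):
        a = mq.mgsem.FitResult("a", 0, 5.0, 10, 0.5, None, True, 0, 100, 2)
        b = mq.mgsem.FitResult("b", 0, 6.0, 8, 0.5, None, True, 0, 100, 2)
        d = chisq_diff(a, b)
        assert d.tdiff == pytest.approx(-1.0)
        assert d.warning is not None


class TestRunSequence:
    def test_df_column(self, literacy_model):
        design = mq.default_design(literacy_model, ns=(78, 174), seed=5)
        data = mq.generate(design, "moments")
        rows = run_sequence(data, literacy_model)
        assert [r.name for r in rows] == [
            "fit.configural.g1", "fit.configural.g2", "fit.combine.groups",
            "fit.metric", "fit.residuals", "fit.varfactor", "fit.scalar",
            "fit.strong.means", "fit.strict.residuals", "fit.strict.means",
        ]
        assert [r.fit.df for r in rows] == [6, 6, 12, 15, 21, 27, 18, 21,
                                            24, 27]

    def test_identical_groups_zero_differences(self, simple_model):
        design = mq.default_design(simple_model, ns=(100, 100), seed=0)
        pop = mq.generate(design, "population")
        rows = run_sequence(pop, simple_model)
        for r in rows:
            assert r.fit.tml == pytest.approx(0.0, abs=1e-5)
            if r.diff is not None:
                assert abs(r.diff.tdiff) < 1e-5

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_nested_t_nondecreasing(self, small_model, seed):
        design = mq.default_design(small_model, ns=(90, 110), seed=seed)
        data = mq.generate(design, "moments")
        rows = {r.name: r.fit for r in run_sequence(data, small_model)}
        chains = [
            ["fit.combine.groups", "fit.metric", "fit.residuals",
             "fit.varfactor"],
            ["fit.combine.groups", "fit.metric", "fit.scalar",
             "fit.strong.means"],
            ["fit.metric", "fit.scalar", "fit.strict.residuals",
             "fit.strict.means"],
        ]
        for chain in chains:
            ts = [rows[name].tml for name in chain]
            for a, b in zip(ts, ts[1:]):
                assert b >= a - 1e-6

    def test_scope_covariance_drops_mean_rows(self, invariant_moments,
                                              simple_model):
        rows = run_sequence(invariant_moments, simple_model,
                            scope="covariance")
        names = [r.name for r in rows]
        assert "fit.scalar" not in names
        assert "fit.strong.means" not in names
        assert "fit.residuals" in names

    def test_scope_mean_drops_covariance_rows(self, invariant_moments,
                                              simple_model):
        names = [r.name for r in run_sequence(invariant_moments,
                                              simple_model, scope="mean")]
        assert "fit.residuals" not in names
        assert "fit.varfactor" not in names
        assert "fit.strict.means" in names

    def test_single_group_rejected(self, invariant_moments, simple_model):
        with pytest.raises(ValueError):
            run_sequence(invariant_moments[:1], simple_model)


class TestCovEqualityTest:
    def test_df_literacy_dimensions(self, literacy_model):
        design = mq.default_design(literacy_model, ns=(78, 174), seed=7)
        data = mq.generate(design, "moments")
        fr = cov_equality_test(data)
        assert fr.df == 21
        assert fr.name == "fit.pop.cov"

    def test_identical_moments_zero(self, simple_model):
        design = mq.default_design(simple_model, ns=(100, 100), seed=0)
        pop = mq.generate(design, "population")
        assert cov_equality_test(pop).tml == pytest.approx(0.0, abs=1e-10)

    def test_against_numeric_constrained_fit(self, rng):
        # independent oracle: optimize a common Cholesky factor numerically
        from scipy.optimize import minimize

        data = []
        for j, n in enumerate((40, 60)):
            a = rng.standard_normal((n, 2)) * (1 + 0.3 * j)
            c = (a - a.mean(0)).T @ (a - a.mean(0)) / n
            data.append(GroupMoments(f"g{j}", n, a.mean(0), c))
        N = sum(g.n for g in data)

        def obj(theta):
            L = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
            sigma = L @ L.T
            sign, ld = np.linalg.slogdet(sigma)
            if sign <= 0:
                return 1e6
            si = np.linalg.inv(sigma)
            f = 0.0
            for gm in data:
                f += gm.n / N * (
                    ld - np.linalg.slogdet(gm.cov)[1]
                    + np.trace(gm.cov @ si) - 2)
            return f

        res = minimize(obj, [1.0, 0.0, 1.0], method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-14,
                                    maxiter=10000, maxfev=10000))
        fr = cov_equality_test(data)
        assert fr.tml == pytest.approx((N - 2) * res.fun, abs=1e-6)

    def test_single_group_rejected(self, simple_model, invariant_moments):
        with pytest.raises(ValueError):
            cov_equality_test(invariant_moments[:1])


class TestConstraintSet:
    def test_unknown_tau_mode(self):
        with pytest.raises(ValueError):
            ConstraintSet("x", tau_mode="bogus")

    def test_latent_means_need_equal_intercepts(self):
        with pytest.raises(ValueError):
            ConstraintSet("x", tau_mode="baseline")

    def test_sequence_nesting(self):
        for name, cs in CONSTRAINT_SETS.items():
            if cs.parent:
                assert cs.is_nested_in(CONSTRAINT_SETS[cs.parent]), name
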