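import numpy as np
import pytest
from scipy import stats

from starchnet.datamodel import ExpressionMatrix, default_diurnal_grid
from starchnet.ggm import (
    CorrelationMatrix,
    correlation_matrix,
    edge_significance,
    fit_mixture,
    null_pcor_cdf,
    null_pcor_density,
    partial_corr_3var,
    partial_corr_full,
    run_ggm,
    shrink_correlation,
)
from starchnet.simulate import make_sparse_ggm, simulate_ggm_matrix


def _matrix_from(values):
    values = np.asarray(values, dtype=float)
    times, phases = default_diurnal_grid(values.shape[1])
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        values=values,
        array_time_h=times,
        array_phase=phases,
    )


def _random_correlation_3x3(rng):
    X = rng.standard_normal((3, 6))
    r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    return 0.5 * (r + r.T)


class TestCorrelationMatrix:
    def test_identical_rows_r_one(self):
        base = np.array([1.0, 2, 3, 1, 5, 2, 0, 4, 2, 1])
        m = _matrix_from([base, base, base * 0.5 + 2])
        c = correlation_matrix(m)
        assert c.r[0, 1] == pytest.approx(1.0)
        assert c.r[0, 2] == pytest.approx(1.0)

    def test_negated_row_r_minus_one(self):
        base = np.array([1.0, 2, 3, 1, 5, 2])
        m = _matrix_from([base, -base])
        c = correlation_matrix(m)
        assert c.r[0, 1] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 12))
        c = correlation_matrix(_matrix_from(X))
        for i in range(5):
            for j in range(5):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert c.r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_rejected(self):
        m = _matrix_from([[1.0, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(m)
        c = correlation_matrix(m, drop_zero_variance=True)
        assert c.gene_ids == ["g1"]


class TestPartialCorrelation:
    def test_no_conditioning_effect(self):
        assert partial_corr_3var(0.4, 0.0, 0.0) == pytest.approx(0.4)

    def test_hand_computed(self):
        # (0.6 - 0.25)/sqrt(0.75*0.75) = 0.35/0.75
        assert partial_corr_3var(0.6, 0.5, 0.5) == pytest.approx(0.35 / 0.75)

    def test_conditional_independence_point(self):
        assert partial_corr_3var(0.3 * 0.4, 0.3, 0.4) == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            partial_corr_3var(0.2, 1.0, 0.3)

    def test_identity_gives_zero_pcors(self):
        net = partial_corr_full(CorrelationMatrix(["a", "b", "c"], np.eye(3)))
        np.testing.assert_allclose(net.pcor, 0.0, atol=1e-15)

    def test_three_variable_cross_oracle(self):
        # matrix-inverse route equals the closed-form 3-variable formula
        rng = np.random.default_rng(1)
        for _ in range(200):
            r = _random_correlation_3x3(rng)
            net = partial_corr_full(CorrelationMatrix(["x", "y", "z"], r))
            expected = partial_corr_3var(r[0, 1], r[0, 2], r[1, 2])
            assert net.pcor[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_block_diagonal_cross_block_zero(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.7
        r[2, 3] = r[3, 2] = -0.5
        net = partial_corr_full(CorrelationMatrix(list("abcd"), r))
        assert abs(net.pcor[0, 2]) < 1e-14
        assert abs(net.pcor[1, 3]) < 1e-14
        assert net.pcor[0, 1] == pytest.approx(0.7)


class TestShrinkage:
    def test_large_n_small_lambda(self):
        truth = make_sparse_ggm(5, n_edges=3, pcor_magnitude=0.3, seed=0,
                                n_planted_regulators=0)
        mat = simulate_ggm_matrix(truth, 1000, seed=1)
        _, lam = shrink_correlation(mat)
        assert lam <= 0.1

    def test_p_much_larger_than_n_invertible(self):
        truth = make_sparse_ggm(133, edge_density=0.03, pcor_magnitude=0.25, seed=2,
                                n_planted_regulators=0)
        mat = simulate_ggm_matrix(truth, 10, seed=3)
        corr, lam = shrink_correlation(mat)
        assert lam > 0
        cond = np.linalg.cond(corr.r)
        assert np.isfinite(cond)
        net = partial_corr_full(corr)  # must not raise
        assert np.all(np.abs(net.offdiag_values()) < 1.0)

    def test_lambda_one_gives_zero_pcors(self):
        r_star = CorrelationMatrix(list("abc"), np.eye(3))  # full shrinkage target
        net = partial_corr_full(r_star)
        np.testing.assert_allclose(net.pcor, 0.0, atol=1e-15)

    def test_pcor_invariant_to_affine_rescaling(self):
        truth = make_sparse_ggm(8, n_edges=6, pcor_magnitude=0.3, seed=4,
                                n_planted_regulators=0)
        mat = simulate_ggm_matrix(truth, 20, seed=5)
        net1 = partial_corr_full(shrink_correlation(mat)[0])
        scaled = ExpressionMatrix(
            gene_ids=mat.gene_ids,
            values=mat.values * np.arange(1, 9)[:, None] + np.arange(8)[:, None],
            array_time_h=mat.array_time_h,
            array_phase=mat.array_phase,
        )
        net2 = partial_corr_full(shrink_correlation(scaled)[0])
        np.testing.assert_allclose(net1.pcor, net2.pcor, atol=1e-10)


class TestMixture:
    def test_kappa_three_is_uniform(self):
        r = np.linspace(-0.99, 0.99, 7)
        np.testing.assert_allclose(null_pcor_density(r, 3.0), 0.5, rtol=1e-12)

    def test_density_integrates_to_one(self):
        from scipy.integrate import quad

        for kappa in (3.0, 10.0, 50.0):
            total, _ = quad(lambda x: null_pcor_density(np.array(x), kappa), -1, 1)
            assert total == pytest.approx(1.0, rel=1e-8)

    def test_parameter_recovery_pure_null(self):
        a = (20 - 1) / 2.0
        r = 2 * stats.beta.rvs(a, a, size=5000, random_state=11) - 1
        fit = fit_mixture(r)
        assert fit.eta0 >= 0.9
        assert 0.7 * 20 <= fit.kappa <= 1.3 * 20

    def test_eta0_recovery_under_contamination(self):
        rng = np.random.default_rng(12)
        a = (20 - 1) / 2.0
        null = 2 * stats.beta.rvs(a, a, size=4500, random_state=13) - 1
        alt = rng.uniform(-1, 1, 500)
        fit = fit_mixture(np.concatenate([null, alt]))
        assert abs(fit.eta0 - 0.9) <= 0.1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_mixture(np.linspace(-0.5, 0.5, 5))

    def test_values_outside_open_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture(np.array([0.0] * 9 + [1.0]))

    def test_null_pvalues_uniform_at_known_kappa_scale(self):
        # direct f0 draws: fitted-null p-values pass the 1% KS bar at m=5000
        a = (30 - 1) / 2.0
        r = 2 * stats.beta.rvs(a, a, size=5000, random_state=14) - 1
        fit = fit_mixture(r)
        p = 2 * (1 - null_pcor_cdf(np.abs(r), fit.kappa))
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 1.63 / np.sqrt(5000)


class TestEdgeSignificance:
    def test_zero_pcor_p_one_and_monotone_tail(self):
        truth = make_sparse_ggm(10, n_edges=8, pcor_magnitude=0.3, seed=6,
                                n_planted_regulators=0)
        mat = simulate_ggm_matrix(truth, 50, seed=7)
        net = run_ggm(mat)
        iu = np.triu_indices(10, k=1)
        pc, pv = np.abs(net.pcor[iu]), net.p_value[iu]
        order = np.argsort(pc)
        assert np.all(np.diff(pv[order]) <= 1e-12)  # larger |pcor| -> smaller p

    def test_edges_match_q_threshold(self):
        truth = make_sparse_ggm(12, n_edges=10, pcor_magnitude=0.35, seed=8,
                                n_planted_regulators=0)
        mat = simulate_ggm_matrix(truth, 100, seed=9)
        net = run_ggm(mat, q_threshold=0.05)
        iu = np.triu_indices(12, k=1)
        n_below = int(np.sum(net.q_value[iu] <= 0.05))
        assert len(net.edges) == n_below

    def test_edges_canonically_ordered(self):
        truth = make_sparse_ggm(12, n_edges=10, pcor_magnitude=0.35, seed=8,
                                n_planted_regulators=0)
        mat = simulate_ggm_matrix(truth, 100, seed=9)
        net = run_ggm(mat)
        assert all(a < b for a, b in net.edges)
        assert net.edges == sorted(net.edges)
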