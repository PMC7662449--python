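import numpy as np
import pytest

from gbckit import (
    CorrelationStructure,
    c_gbc,
    combined_determination,
    correlation_structure,
    d_gbc,
    estimate_path_gbc,
    path_from_regression,
    residual_determination,
    solve_bivariate,
    solve_path_coefficients,
)
from conftest import random_freq_table

BEEFMASTER_P = np.array([np.sqrt(2.0), 1.0, 1.0]) * 0.5  # 2p^2 : p^2 : p^2
BEEFMASTER_R = np.array([[1.0, 0.10, 0.05], [0.10, 1.0, 0.40], [0.05, 0.40, 1.0]])


def _random_instance(seed, K, M):
    rng = np.random.default_rng(seed)
    F = random_freq_table(rng, M, K)
    w = rng.dirichlet(np.ones(K))
    y = np.clip(F.freq @ w + rng.normal(0, 0.1, M), 0, 1)
    return y, F


class TestSolvePathCoefficients:
    def test_identity_correlations_pass_through(self):
        cs = CorrelationStructure(["a", "b"], [0.6, 0.3], np.eye(2), "pearson", 100)
        sol = solve_path_coefficients(cs)
        np.testing.assert_allclose(sol.p_yx, [0.6, 0.3])

    def test_bivariate_closed_form_agreement(self, rng):
        for _ in range(10):
            r12 = rng.uniform(-0.8, 0.8)
            ry = rng.uniform(-0.9, 0.9, 2)
            cs = CorrelationStructure(
                ["a", "b"], ry, np.array([[1, r12], [r12, 1]]), "pearson", 100
            )
            sol = solve_path_coefficients(cs)
            p1, p2 = solve_bivariate(ry[0], ry[1], r12)
            np.testing.assert_allclose(sol.p_yx, [p1, p2], atol=1e-12)

    def test_reconstruction_identity(self, rng):
        y, F = _random_instance(11, 5, 400)
        sol = solve_path_coefficients(correlation_structure(y, F))
        np.testing.assert_allclose(sol.R_xx @ sol.p_yx, sol.r_yx, atol=1e-10)

    def test_singular_matrix_reports_pair(self):
        R = np.array([[1.0, 1.0 - 1e-12], [1.0 - 1e-12, 1.0]])
        cs = CorrelationStructure(["angus", "clone"], [0.5, 0.5], R, "pearson", 10)
        with pytest.raises(np.linalg.LinAlgError, match="angus ~ clone"):
            solve_path_coefficients(cs)


class TestSolveBivariate:
    def test_uncorrelated_passthrough(self):
        assert solve_bivariate(0.6, 0.3, 0.0) == (0.6, 0.3)

    def test_worked_values(self):
        p1, p2 = solve_bivariate(0.6, 0.5, 0.4)
        assert p1 == pytest.approx(0.476190, abs=1e-6)
        assert p2 == pytest.approx(0.309524, abs=1e-6)

    def test_matches_matrix_solve_oracle(self, rng):
        ry1, ry2, r12 = 0.55, -0.2, 0.33
        expect = np.linalg.solve(np.array([[1, r12], [r12, 1]]), [ry1, ry2])
        np.testing.assert_allclose(solve_bivariate(ry1, ry2, r12), expect, atol=1e-14)

    def test_perfect_collinearity_errors(self):
        with pytest.raises(np.linalg.LinAlgError):
            solve_bivariate(0.5, 0.5, 1.0)


class TestDualRoute:
    @pytest.mark.parametrize("seed", range(5))
    def test_regression_route_equals_correlation_route(self, seed):
        rng = np.random.default_rng(100 + seed)
        K = int(rng.integers(2, 9))
        M = int(rng.integers(100, 2001))
        y, F = _random_instance(200 + seed, K, M)
        sol_corr = solve_path_coefficients(correlation_structure(y, F))
        sol_reg = path_from_regression(y, F.freq)
        np.testing.assert_allclose(sol_reg.p_yx, sol_corr.p_yx, atol=1e-8)
        np.testing.assert_allclose(sol_reg.combined_det, sol_corr.combined_det, atol=1e-8)

    def test_standardized_target_uncorrelated_columns(self, rng):
        # y equal to x1, x's orthogonalized -> p = (1, 0)
        M = 200
        x1 = rng.uniform(0, 1, M)
        x2 = rng.uniform(0, 1, M)
        x2 = x2 - np.polyval(np.polyfit(x1, x2, 1), x1) + x2.mean()  # decorrelate
        sol = path_from_regression(x1.copy(), np.column_stack([x1, x2]))
        np.testing.assert_allclose(sol.p_yx, [1.0, 0.0], atol=1e-10)

    def test_exact_linear_combination_has_zero_residual(self, rng):
        F = random_freq_table(rng, 300, 3)
        y = F.freq @ np.array([0.5, 0.3, 0.2])
        sol = path_from_regression(y, F.freq)
        assert sol.residual_det == pytest.approx(0.0, abs=1e-10)
        assert sol.p_ye == pytest.approx(0.0, abs=1e-5)
        assert sol.reliability == pytest.approx(1.0, abs=1e-10)


class TestCombinedDetermination:
    def test_beefmaster_worked_components(self):
        d = combined_determination(BEEFMASTER_P, BEEFMASTER_R)
        np.testing.assert_allclose(
            d, [0.553033, 0.385355, 0.367678], atol=1e-6
        )

    def test_identity_reduces_to_squares(self, rng):
        p = rng.normal(0, 0.5, 4)
        np.testing.assert_allclose(combined_determination(p, np.eye(4)), p**2)

    def test_sum_equals_quadratic_form(self, rng):
        for _ in range(10):
            K = int(rng.integers(2, 7))
            A = rng.normal(0, 1, (K, K))
            R = A @ A.T
            dd = 1 / np.sqrt(np.diag(R))
            R = dd[:, None] * R * dd[None, :]
            np.fill_diagonal(R, 1.0)
            p = rng.normal(0, 0.5, K)
            assert combined_determination(p, R).sum() == pytest.approx(
                p @ R @ p, abs=1e-12
            )


class TestGBCRatios:
    def test_d_gbc_from_printed_coefficients(self):
        est = d_gbc(np.array([0.668, 0.418]))
        np.testing.assert_allclose(np.round(est.composition, 3), [0.719, 0.281])

    def test_d_gbc_degenerate_and_unit_cases(self):
        assert d_gbc(np.array([0.4])).composition.tolist() == [1.0]
        np.testing.assert_allclose(d_gbc(np.array([0.6, 0.8])).composition, [0.36, 0.64])
        with pytest.raises(ValueError):
            d_gbc(np.zeros(3))

    def test_c_gbc_beefmaster_worked_example(self):
        est = c_gbc(BEEFMASTER_P, BEEFMASTER_R)
        np.testing.assert_allclose(np.round(est.composition, 3), [0.423, 0.295, 0.282])
        assert est.composition.sum() == pytest.approx(1.0, abs=1e-12)

    def test_c_gbc_zero_correlation_equals_d_gbc(self):
        p = BEEFMASTER_P
        np.testing.assert_allclose(
            c_gbc(p, np.eye(3)).composition, d_gbc(p).composition, atol=1e-12
        )
        np.testing.assert_allclose(
            c_gbc(p, np.eye(3)).composition, [0.5, 0.25, 0.25], atol=1e-12
        )

    def test_c_gbc_clamps_negative_components(self):
        p = np.array([0.9, 0.05])
        R = np.array([[1.0, -0.8], [-0.8, 1.0]])
        # second combined component is negative: 0.0025 - 0.8*0.05*0.9 < 0
        est = c_gbc(p, R)
        assert est.clamped
        assert (est.composition >= 0).all()
        assert est.composition.sum() == pytest.approx(1.0, abs=1e-12)


class TestResidualDetermination:
    def test_beefmaster_negative_residual_warns(self):
        with pytest.warns(UserWarning, match="residual"):
            R, p_ye, rel = residual_determination(BEEFMASTER_P, BEEFMASTER_R)
        assert R == pytest.approx(1 - 1.306066, abs=1e-6)
        assert p_ye == 0.0
        assert rel == pytest.approx(1.306066, abs=1e-6)

    def test_noisy_instances_keep_residual_in_unit_interval(self):
        for seed in range(30):
            y, F = _random_instance(300 + seed, 3, 250)
            sol = solve_path_coefficients(correlation_structure(y, F))
            assert -1e-10 <= sol.residual_det <= 1.0

    def test_decomposition_identity(self):
        for seed in range(10):
            y, F = _random_instance(400 + seed, 4, 300)
            sol = solve_path_coefficients(correlation_structure(y, F))
            assert sol.combined_det.sum() + sol.residual_det == pytest.approx(
                1.0, abs=1e-10
            )


class TestEstimatePathGBC:
    def test_single_breed_target_is_pure(self, rng):
        F = random_freq_table(rng, 200, 3)
        est = estimate_path_gbc(F.freq[:, 1].copy(), F, mode="direct")
        assert est.composition[1] == pytest.approx(1.0, abs=1e-9)

    def test_direct_close_to_combined_when_breeds_unrelated(self, scenarios):
        sc = scenarios["brangus_like"]
        pooled = sc.genotypes.dosage.mean(axis=0) / 2.0
        d = estimate_path_gbc(pooled, sc.frequencies, mode="direct").composition
        c = estimate_path_gbc(pooled, sc.frequencies, mode="combined").composition
        assert np.abs(d - c).max() <= 0.02

    def test_correlated_pair_widens_direct_combined_gap(self, scenarios):
        bl = scenarios["brangus_like"]
        bm = scenarios["beefmaster_like"]

        def gap(sc):
            pooled = sc.genotypes.dosage.mean(axis=0) / 2.0
            d = estimate_path_gbc(pooled, sc.frequencies, mode="direct").composition
            c = estimate_path_gbc(pooled, sc.frequencies, mode="combined").composition
            return abs(d[0] - c[0])

        assert gap(bm) > gap(bl)

    def test_reliability_attached_and_spearman_mode(self, scenarios):
        sc = scenarios["brangus_like"]
        est = estimate_path_gbc(
            sc.genotypes.dosage[0], sc.frequencies, method="spearman", mode="combined"
        )
        assert est.reliability is not None
        assert est.n_loci == sc.frequencies.n_snps
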