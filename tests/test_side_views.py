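"""Kernels, guidance matrices, Laplacian identities, and the consistency test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gmsv.side_views import (
    KernelMatrix,
    SideView,
    build_guidance,
    build_laplacian,
    consistency_test,
    minmax_normalize,
    omega_matrix,
    rbf_kernel,
    theta_matrix,
)
from gmsv.synthetic import ViewSpec, sample_views


class TestMinMax:
    def test_columns_rescaled(self):
        x = np.array([[0.0, 2.0], [5.0, 4.0], [10.0, 7.0]])
        out = minmax_normalize(x)
        np.testing.assert_allclose(out[:, 0], [0, 0.5, 1])
        np.testing.assert_allclose(out[:, 1], [0, 0.4, 1])

    def test_constant_column_maps_to_zero(self):
        out = minmax_normalize(np.array([[3.0], [3.0], [3.0]]))
        np.testing.assert_array_equal(out, np.zeros((3, 1)))


class TestRBF:
    def test_identical_rows_give_unit_similarity(self):
        view = SideView(np.ones((3, 4)))
        kern = rbf_kernel(view)
        np.testing.assert_allclose(kern.kappa, np.ones((3, 3)))
        assert kern.mu == pytest.approx(1.0)

    def test_bandwidth_scales_with_dimensionality(self):
        one_d = rbf_kernel(SideView(np.array([[0.0], [1.0]])))
        assert one_d.kappa[0, 1] == pytest.approx(np.exp(-1.0))
        two_d = rbf_kernel(SideView(np.array([[0.0, 0.0], [1.0, 1.0]])))
        assert two_d.kappa[0, 1] == pytest.approx(np.exp(-1.0))

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        kern = rbf_kernel(SideView(rng.normal(size=(6, 3))))
        np.testing.assert_allclose(kern.kappa, kern.kappa.T)
        np.testing.assert_allclose(np.diag(kern.kappa), 1.0)
        assert np.all(kern.kappa > 0) and np.all(kern.kappa <= 1)


class TestTheta:
    def test_two_subject_hand_example(self):
        kern = KernelMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), mu=0.75)
        theta = theta_matrix(kern)
        np.testing.assert_allclose(theta, [[0.5, -0.5], [-0.5, 0.5]])

    def test_normalization_balances_the_two_sets(self):
        rng = np.random.default_rng(1)
        kern = rbf_kernel(SideView(rng.normal(size=(7, 3))))
        theta = theta_matrix(kern)
        assert theta[theta > 0].sum() == pytest.approx(1.0)
        assert theta[theta < 0].sum() == pytest.approx(-1.0)
        assert theta.sum() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(theta, theta.T)

    def test_constant_kernel_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            theta_matrix(KernelMatrix(np.ones((3, 3)), mu=1.0))


class TestOmega:
    def test_two_subject_hand_example(self):
        omega = omega_matrix(np.array([1, -1]))
        np.testing.assert_allclose(omega, [[0.5, -0.5], [-0.5, 0.5]])

    def test_pair_counts_include_diagonal_and_order(self):
        omega = omega_matrix(np.array([1, 1, -1]))
        # |M| = 5 ordered same-label pairs (incl. diagonal), |C| = 4
        assert omega[0, 0] == pytest.approx(1 / 5)
        assert omega[0, 2] == pytest.approx(-1 / 4)
        assert omega[omega > 0].sum() == pytest.approx(1.0)
        assert omega[omega < 0].sum() == pytest.approx(-1.0)

    def test_all_unlabeled_gives_zero_matrix(self):
        np.testing.assert_array_equal(omega_matrix(np.zeros(4)), np.zeros((4, 4)))

    def test_unlabeled_rows_are_zero(self):
        omega = omega_matrix(np.array([1, 0, -1]))
        assert np.all(omega[1, :] == 0) and np.all(omega[:, 1] == 0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="one class"):
            omega_matrix(np.array([1, 1, 1]))


class TestLaplacian:
    def test_zero_view_weights_reduce_to_supervision(self):
        omega = omega_matrix(np.array([1, -1]))
        theta = np.array([[0.2, -0.2], [-0.2, 0.2]])
        lap = build_laplacian(omega, [theta], [0.0])
        np.testing.assert_allclose(lap.phi, omega)

    def test_hand_example_L_and_clipped_L(self):
        phi = np.array([[0.5, -0.5], [-0.5, 0.5]])
        lap = build_laplacian(phi)  # omega alone
        np.testing.assert_allclose(lap.degree, [0.0, 0.0])
        np.testing.assert_allclose(lap.L, [[-0.5, 0.5], [0.5, -0.5]])
        np.testing.assert_allclose(lap.L_hat, [[-0.5, 0.0], [0.0, -0.5]])

    def test_row_sums_zero_and_clip_inequalities(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            phi = rng.normal(size=(6, 6))
            phi = (phi + phi.T) / 2
            lap = build_laplacian(phi)
            np.testing.assert_allclose(lap.L.sum(axis=1), 0.0, atol=1e-12)
            assert np.all(lap.L_hat <= lap.L + 1e-15)
            assert np.all(lap.L_hat <= 0)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            build_laplacian(np.zeros((3, 3)), [np.zeros((2, 2))], [1.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_quadratic_form_identity(self, seed):
        """fᵀLf = ½·Σ_ij Φ_ij (f_i − f_j)² for any binary f and symmetric Φ."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        phi = rng.normal(size=(n, n))
        phi = (phi + phi.T) / 2
        lap = build_laplacian(phi)
        f = rng.integers(0, 2, size=n).astype(float)
        lhs = f @ lap.L @ f
        rhs = 0.5 * sum(
            phi[i, j] * (f[i] - f[j]) ** 2 for i in range(n) for j in range(n)
        )
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_phi_diagonal_does_not_affect_quadratic_form(self):
        rng = np.random.default_rng(5)
        phi = rng.normal(size=(5, 5))
        phi = (phi + phi.T) / 2
        bumped = phi + np.diag(rng.normal(size=5))
        f = np.array([1.0, 0, 1, 1, 0])
        q1 = f @ build_laplacian(phi).L @ f
        q2 = f @ build_laplacian(bumped).L @ f
        assert q1 == pytest.approx(q2, abs=1e-9)

    def test_build_guidance_rejects_empty_guidance(self):
        view = SideView(np.random.default_rng(0).normal(size=(4, 2)), weight=0.0)
        with pytest.raises(ValueError, match="empty"):
            build_guidance(None, [view])
        with pytest.raises(ValueError, match="empty"):
            build_guidance(np.zeros(4), [view])


class TestConsistencyTest:
    def test_identical_samples_are_uninformative(self):
        # a constant kernel off-diagonal: both groups sample the same values
        kappa = np.full((4, 4), 0.5)
        np.fill_diagonal(kappa, 1.0)
        t, p = consistency_test(KernelMatrix(kappa, 0.5), np.array([1, 1, -1, -1]), seed=0)
        assert t == 0.0 and p == 0.5

    def test_single_class_errors(self):
        kern = rbf_kernel(SideView(np.random.default_rng(0).normal(size=(4, 2))))
        with pytest.raises(ValueError):
            consistency_test(kern, np.array([1, 1, 1, 1]), seed=0)

    def test_strong_separation_rejects(self):
        labels = np.concatenate([np.ones(15, int), -np.ones(15, int)])
        rng = np.random.default_rng(9)
        views, _ = sample_views(labels, [ViewSpec(6, 4.0, 1.0)], rng)
        kern = rbf_kernel(SideView(minmax_normalize(views[0].features)))
        t, p = consistency_test(kern, labels, seed=1)
        assert t > 0 and p < 0.01

    def test_pooled_variant_available_and_seed_reproducible(self):
        labels = np.concatenate([np.ones(10, int), -np.ones(10, int)])
        rng = np.random.default_rng(4)
        views, _ = sample_views(labels, [ViewSpec(4, 1.0, 1.0)], rng)
        kern = rbf_kernel(SideView(views[0].features))
        welch = consistency_test(kern, labels, seed=3)
        pooled = consistency_test(kern, labels, seed=3, equal_var=True)
        assert consistency_test(kern, labels, seed=3) == welch
        assert welch != pooled  # same draws, different variance model
        assert 0 <= welch[1] <= 1 and 0 <= pooled[1] <= 1
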