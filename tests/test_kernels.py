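"""Kernel construction: exact identities, brute-force oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcgp.kernels import (
    EnvironmentDesign,
    KernelError,
    KernelMatrix,
    MarkerMatrix,
    arc_cosine_kernel,
    arc_cosine_layer1,
    arc_cosine_step,
    center_scale,
    expand_to_observations,
    gaussian_kernel,
    ge_interaction_kernel,
    j_theta,
    linear_kernel,
    squared_distance_matrix,
)


def brute_linear(X):
    n, p = X.shape
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = sum(X[i, k] * X[j, k] for k in range(p)) / p
    return K


def brute_sqdist(X):
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = sum((X[i, k] - X[j, k]) ** 2 for k in range(X.shape[1]))
    return D


def brute_ak1(X):
    n = X.shape[0]
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ni, nj = np.linalg.norm(X[i]), np.linalg.norm(X[j])
            c = np.clip(X[i] @ X[j] / (ni * nj), -1, 1)
            th = np.arccos(c)
            K[i, j] = ni * nj * (np.sin(th) + (np.pi - th) * np.cos(th)) / np.pi
    return K


def brute_ak_step(K):
    n = K.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            norm = np.sqrt(K[i, i] * K[j, j])
            th = np.arccos(np.clip(K[i, j] / norm, -1, 1))
            out[i, j] = norm * (np.sin(th) + (np.pi - th) * np.cos(th)) / np.pi
    return out


class TestCenterScale:
    def test_three_point_column(self):
        M = MarkerMatrix(np.array([[0.0], [1.0], [2.0]]), ["a", "b", "c"], ["f"])
        out = center_scale(M)
        np.testing.assert_allclose(out.values[:, 0], [-1, 0, 1], atol=1e-12)
        assert out.scaled

    def test_constant_column_dropped_with_warning(self):
        M = MarkerMatrix(
            np.array([[2.0, 1.0], [2.0, 2.0], [2.0, 3.0]]), list("abc"), ["c1", "c2"]
        )
        with pytest.warns(UserWarning, match="constant"):
            out = center_scale(M)
        assert out.feature_ids == ["c2"]

    def test_all_constant_errors(self):
        M = MarkerMatrix(np.full((3, 2), 1.0), list("abc"), ["c1", "c2"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no informative"):
                center_scale(M)

    def test_column_moments(self, dosage_markers):
        out = center_scale(dosage_markers)
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestLinearKernel:
    def test_two_opposite_rows(self):
        M = MarkerMatrix(np.array([[1.0], [-1.0]]), ["a", "b"], ["f"])
        np.testing.assert_allclose(linear_kernel(M).values, [[1, -1], [-1, 1]])

    def test_zero_matrix(self):
        M = MarkerMatrix(np.zeros((3, 4)), list("abc"), list("wxyz"))
        np.testing.assert_allclose(linear_kernel(M).values, 0.0)

    def test_against_double_loop(self, small_markers):
        K = linear_kernel(small_markers)
        np.testing.assert_allclose(K.values, brute_linear(small_markers.values),
                                   rtol=1e-10)
        assert K.kind == "GB"


class TestSquaredDistance:
    def test_three_four_five(self):
        M = MarkerMatrix(np.array([[0.0, 0.0], [3.0, 4.0]]), ["a", "b"], ["x", "y"])
        D, q = squared_distance_matrix(M)
        assert D[0, 1] == pytest.approx(25.0)
        assert q == pytest.approx(25.0)
        assert D[0, 0] == 0.0

    def test_identical_rows_zero_median(self):
        M = MarkerMatrix(np.ones((3, 2)), list("abc"), ["x", "y"])
        D, q = squared_distance_matrix(M)
        assert q == 0.0 and np.all(D == 0)

    def test_against_double_loop(self, rng):
        X = rng.standard_normal((6, 4))
        M = MarkerMatrix(X, [f"L{i}" for i in range(6)], list("abcd"))
        D, _ = squared_distance_matrix(M)
        np.testing.assert_allclose(D, brute_sqdist(X), rtol=1e-10, atol=1e-12)


class TestGaussianKernel:
    def test_diagonal_one_and_range(self, small_markers):
        K = gaussian_kernel(small_markers, h=1.0)
        np.testing.assert_array_equal(np.diag(K.values), 1.0)
        assert np.all(K.values > 0) and np.all(K.values <= 1)
        assert K.kind == "GK" and K.params["h"] == 1.0

    def test_small_h_limit(self, small_markers):
        K = gaussian_kernel(small_markers, h=1e-10)
        np.testing.assert_allclose(K.values, 1.0, atol=1e-8)

    def test_median_pair_value(self):
        # three collinear points: the middle distance is the median
        M = MarkerMatrix(np.array([[0.0], [1.0], [3.0]]), list("abc"), ["x"])
        _, q = squared_distance_matrix(M)
        K = gaussian_kernel(M, h=1.0)
        # pair (a,c) has d^2 = 9; median q of {1, 4, 9} is 4
        assert K.values[0, 2] == pytest.approx(np.exp(-9.0 / q))
        assert K.values[0, 1] == pytest.approx(np.exp(-1.0 / q))

    def test_degenerate_distances_rejected(self):
        M = MarkerMatrix(np.ones((3, 2)), list("abc"), ["x", "y"])
        with pytest.raises(KernelError, match="degenerate"):
            gaussian_kernel(M, h=1.0)

    def test_monotone_in_h_and_distance(self, small_markers):
        D, q = squared_distance_matrix(small_markers)
        K1 = gaussian_kernel(small_markers, 0.5).values
        K2 = gaussian_kernel(small_markers, 2.0).values
        off = ~np.eye(8, dtype=bool)
        assert np.all(K2[off] < K1[off])  # larger h decays faster
        i, j = np.unravel_index(np.argmax(D), D.shape)
        a, b = np.unravel_index(np.argmin(D + np.eye(8) * D.max()), D.shape)
        assert K1[i, j] < K1[a, b]  # larger distance, smaller similarity


class TestArcCosine:
    def test_j_boundary_values(self):
        np.testing.assert_allclose(
            j_theta([0.0, np.pi / 2, np.pi]), [np.pi, 1.0, 0.0], atol=1e-12
        )

    @given(st.floats(0.0, np.pi))
    @settings(max_examples=50, deadline=None)
    def test_j_nonnegative(self, theta):
        assert j_theta(theta) >= -1e-12

    def test_self_similarity_is_squared_norm(self):
        M = MarkerMatrix(np.array([[1.0, 2, 3], [0.0, 0, 1]]), ["a", "b"], list("xyz"))
        K = arc_cosine_layer1(M)
        assert K.values[0, 0] == pytest.approx(14.0)

    def test_antipodal_pair_is_zero(self):
        M = MarkerMatrix(np.array([[1.0, 2, 3], [-1.0, -2, -3]]), ["a", "b"],
                         list("xyz"))
        assert arc_cosine_layer1(M).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pair(self):
        M = MarkerMatrix(np.array([[2.0, 0.0], [0.0, 3.0]]), ["a", "b"], ["x", "y"])
        assert arc_cosine_layer1(M).values[0, 1] == pytest.approx(6.0 / np.pi)

    def test_quarter_angle_closed_form(self):
        # x=(1,0), x'=(1,1): theta=pi/4, AK1 = 1/pi + 3/4
        M = MarkerMatrix(np.array([[1.0, 0.0], [1.0, 1.0]]), ["a", "b"], ["x", "y"])
        assert arc_cosine_layer1(M).values[0, 1] == pytest.approx(1 / np.pi + 0.75)

    def test_zero_norm_row_names_line(self):
        M = MarkerMatrix(np.array([[0.0, 0.0], [1.0, 1.0]]), ["bad", "ok"], ["x", "y"])
        with pytest.raises(KernelError, match="bad"):
            arc_cosine_layer1(M)

    def test_against_double_loop(self, small_markers):
        K = arc_cosine_layer1(small_markers)
        np.testing.assert_allclose(K.values, brute_ak1(small_markers.values),
                                   rtol=1e-10, atol=1e-12)

    def test_diagonal_fixed_point_over_layers(self, small_markers):
        norms2 = np.sum(small_markers.values**2, axis=1)
        for l in range(1, 11):
            K = arc_cosine_kernel(small_markers, l)
            np.testing.assert_allclose(np.diag(K.values), norms2, rtol=1e-10)
            K.validate()  # symmetric PSD at every depth

    def test_step_zero_entry_unit_diagonal(self):
        K = KernelMatrix(np.eye(2), ["a", "b"], kind="AK", params={"l": 1})
        out = arc_cosine_step(K)
        assert out.values[0, 1] == pytest.approx(1 / np.pi)
        assert out.params["l"] == 2

    def test_step_against_double_loop(self, small_markers):
        K1 = arc_cosine_layer1(small_markers)
        K2 = arc_cosine_step(K1)
        np.testing.assert_allclose(K2.values, brute_ak_step(K1.values),
                                   rtol=1e-10, atol=1e-12)

    def test_step_requires_positive_diagonal(self):
        K = KernelMatrix(np.diag([1.0, 0.0]), ["a", "b"], kind="AK")
        with pytest.raises(KernelError, match="diagonal"):
            arc_cosine_step(K)

    def test_recursion_composes(self, small_markers):
        K3 = arc_cosine_kernel(small_markers, 3)
        manual = arc_cosine_step(arc_cosine_step(arc_cosine_layer1(small_markers)))
        np.testing.assert_allclose(K3.values, manual.values, rtol=1e-12)
        assert K3.params["l"] == 3
        np.testing.assert_allclose(
            arc_cosine_kernel(small_markers, 1).values,
            arc_cosine_layer1(small_markers).values,
        )


class TestObservationKernels:
    def _design(self):
        # 3 envs x 4 lines, one cell missing
        lines = [0, 1, 2, 3, 0, 1, 2, 3, 0, 1, 3]
        envs = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2]
        return EnvironmentDesign(lines, envs, [f"L{i}" for i in range(4)],
                                 ["E1", "E2", "E3"])

    def test_identity_expansion(self, small_markers):
        K = linear_kernel(small_markers)
        d = EnvironmentDesign(np.arange(8), np.zeros(8, int), K.line_ids, ["E1"])
        np.testing.assert_array_equal(expand_to_observations(K, d), K.values)

    def test_repeated_line_constant_block(self, small_markers):
        K = linear_kernel(small_markers)
        d = EnvironmentDesign([0, 0], [0, 1], K.line_ids, ["E1", "E2"])
        B = expand_to_observations(K, d)
        np.testing.assert_allclose(B, K.values[0, 0])

    def test_expansion_matches_dense_product(self, rng):
        X = rng.standard_normal((4, 6))
        K = linear_kernel(MarkerMatrix(X, [f"L{i}" for i in range(4)],
                                       [f"f{j}" for j in range(6)]))
        d = self._design()
        Zg, _ = d.incidence_matrices()
        np.testing.assert_allclose(
            expand_to_observations(K, d), Zg @ K.values @ Zg.T, rtol=1e-12
        )

    def test_missing_line_named(self, small_markers):
        K = linear_kernel(small_markers)
        d = EnvironmentDesign([0, 1], [0, 0], ["L0", "QQ"], ["E1"])
        with pytest.raises(KernelError, match="QQ"):
            expand_to_observations(K, d)

    def test_interaction_single_env_identity(self, small_markers):
        K = linear_kernel(small_markers)
        d = EnvironmentDesign(np.arange(8), np.zeros(8, int), K.line_ids, ["E1"])
        K1 = expand_to_observations(K, d)
        np.testing.assert_array_equal(ge_interaction_kernel(K1, d), K1)

    def test_interaction_matches_hadamard_oracle(self, rng):
        X = rng.standard_normal((4, 6))
        K = linear_kernel(MarkerMatrix(X, [f"L{i}" for i in range(4)],
                                       [f"f{j}" for j in range(6)]))
        d = self._design()
        K1 = expand_to_observations(K, d)
        _, Ze = d.incidence_matrices()
        np.testing.assert_allclose(ge_interaction_kernel(K1, d), K1 * (Ze @ Ze.T))

    def test_cross_environment_entries_zero(self, small_markers):
        K = linear_kernel(small_markers)
        d = EnvironmentDesign([0, 0], [0, 1], K.line_ids, ["E1", "E2"])
        K2 = ge_interaction_kernel(expand_to_observations(K, d), d)
        assert K2[0, 1] == 0.0 and K2[0, 0] != 0.0


class TestValidation:
    def test_asymmetric_rejected(self):
        K = KernelMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), ["a", "b"])
        with pytest.raises(KernelError, match="symmetric"):
            K.validate()

    def test_indefinite_rejected(self):
        K = KernelMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]), ["a", "b"])
        with pytest.raises(KernelError, match="PSD"):
            K.validate()

    def test_all_kernel_builders_psd(self, dosage_markers):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Ms = center_scale(dosage_markers)
        for K in (linear_kernel(Ms), gaussian_kernel(Ms, 1.0),
                  arc_cosine_kernel(Ms, 4)):
            K.validate()

    def test_design_rejects_duplicate_cell(self):
        with pytest.raises(ValueError, match="duplicate"):
            EnvironmentDesign([0, 0], [0, 0], ["a"], ["E1"])
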