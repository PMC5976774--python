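"""Unit tests for the covariance-difference eigenproblem."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpca.core import (
    ContrastiveModel,
    CovariancePair,
    DataMatrix,
    contrastive_matrix,
    empirical_covariance,
    fit,
    fit_cpca,
    fit_cpca_infinite_alpha,
    transform,
    variance_pair,
)
from cpca.alpha_select import max_principal_angle

from conftest import random_cov_pair, random_dataset_pair


def brute_force_covariance(rows):
    """Independent oracle: direct summation of the defining formula."""
    rows = np.asarray(rows, dtype=float)
    mean = rows.mean(axis=0)
    d = rows.shape[1]
    c = np.zeros((d, d))
    for x in rows:
        c += np.outer(x - mean, x - mean)
    return c / rows.shape[0]


class TestEmpiricalCovariance:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            ([(1, 0), (-1, 0)], [[1, 0], [0, 0]]),
            ([(3, -2)] * 4, [[0, 0], [0, 0]]),  # repeated row: no variance
            # hand/oracle value: mean (1, 1/3) -> diag(2/3, 2/9)
            ([(0, 0), (1, 1), (2, 0)], [[2 / 3, 0], [0, 2 / 9]]),
        ],
    )
    def test_examples(self, rows, expected):
        got = empirical_covariance(DataMatrix.from_array(np.array(rows, float)))
        np.testing.assert_allclose(got, expected, atol=1e-12)
        np.testing.assert_allclose(got, brute_force_covariance(rows), atol=1e-12)

    def test_matches_brute_force_on_random_data(self, rng):
        rows = rng.standard_normal((17, 4)) * 3 + 1
        got = empirical_covariance(DataMatrix.from_array(rows))
        np.testing.assert_allclose(got, brute_force_covariance(rows), atol=1e-10)

    def test_nan_rejected_naming_feature(self):
        values = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="gene_b"):
            DataMatrix(values, ["gene_a", "gene_b"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            DataMatrix(np.empty((0, 2)), ["a", "b"])


class TestContrastiveMatrix:
    def setup_method(self):
        self.cov = CovariancePair(np.diag([4.0, 1.0]), np.diag([1.0, 3.0]), 10, 10)

    def test_diagonal_arithmetic(self):
        np.testing.assert_allclose(
            contrastive_matrix(self.cov, 1.0), np.diag([3.0, -2.0])
        )

    def test_alpha_zero_is_target_covariance(self):
        np.testing.assert_allclose(contrastive_matrix(self.cov, 0.0), self.cov.c_x)

    def test_elementwise_oracle(self, rng):
        cov = random_cov_pair(rng, 5)
        got = contrastive_matrix(cov, 0.5)
        expected = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                expected[i, j] = cov.c_x[i, j] - 0.5 * cov.c_y[i, j]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            CovariancePair(np.eye(2), np.eye(3), 5, 5)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            contrastive_matrix(self.cov, -0.1)


class TestFitCpca:
    def test_diagonal_case(self):
        cov = CovariancePair(np.diag([4.0, 1.0]), np.diag([1.0, 3.0]), 10, 10)
        model = fit_cpca(cov, alpha=1.0, k=1)
        np.testing.assert_allclose(model.components[:, 0], [1.0, 0.0], atol=1e-12)
        assert model.eigenvalues[0] == pytest.approx(3.0)

    def test_alpha_zero_matches_pca_subspace(self, rng):
        from sklearn.decomposition import PCA

        target, background = random_dataset_pair(rng, 80, 60, 12)
        model = fit(target, background, alpha=0.0, k=2)
        ref = PCA(n_components=2).fit(target.values).components_.T
        assert max_principal_angle(model.components, ref) < 1e-8

    def test_first_cpc_beats_monte_carlo_search(self, rng):
        cov = random_cov_pair(rng, 6)
        alpha = 10.0
        model = fit_cpca(cov, alpha, k=1)
        dirs = rng.standard_normal((100_000, 6))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        objectives = (
            np.einsum("nd,de,ne->n", dirs, cov.c_x, dirs)
            - alpha * np.einsum("nd,de,ne->n", dirs, cov.c_y, dirs)
        )
        assert model.eigenvalues[0] >= objectives.max() - 1e-10

    def test_invalid_k_and_alpha_rejected(self, rng):
        cov = random_cov_pair(rng, 3)
        with pytest.raises(ValueError):
            fit_cpca(cov, alpha=1.0, k=4)
        with pytest.raises(ValueError):
            fit_cpca(cov, alpha=-1.0, k=1)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_components_orthonormal_eigenvalues_descending(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 9))
        cov = random_cov_pair(rng, d)
        k = int(rng.integers(1, d + 1))
        model = fit_cpca(cov, alpha=float(rng.uniform(0, 20)), k=k)
        np.testing.assert_allclose(
            model.components.T @ model.components, np.eye(k), atol=1e-8
        )
        assert np.all(np.diff(model.eigenvalues) <= 1e-10)

    def test_sign_convention_deterministic(self, rng):
        cov = random_cov_pair(rng, 5)
        model = fit_cpca(cov, alpha=2.0, k=3)
        for j in range(3):
            col = model.components[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestInfiniteAlpha:
    def test_nullspace_is_second_axis(self):
        # background varies only along axis 1 -> null space is span{e2}
        background = DataMatrix.from_array(np.array([[1.0, 0], [-1.0, 0], [2.0, 0]]))
        target = DataMatrix.from_array(
            np.array([[1.0, 2.0], [-1.0, -2.0], [0.5, 1.0]])
        )
        model = fit_cpca_infinite_alpha(target, background, k=1)
        np.testing.assert_allclose(
            np.abs(model.components[:, 0]), [0.0, 1.0], atol=1e-10
        )
        assert math.isinf(model.alpha)

    def test_zero_background_reduces_to_pca(self, rng):
        from sklearn.decomposition import PCA

        target = DataMatrix.from_array(rng.standard_normal((30, 4)) * [3, 2, 1, 0.5])
        background = DataMatrix.from_array(np.zeros((10, 4)))
        model = fit_cpca_infinite_alpha(target, background, k=2)
        ref = PCA(n_components=2).fit(target.values).components_.T
        assert max_principal_angle(model.components, ref) < 1e-8

    def test_large_alpha_limit(self, rng):
        # rank-2 background covariance in R^5
        background = DataMatrix.from_array(
            rng.standard_normal((200, 2)) @ rng.standard_normal((2, 5))
        )
        target = DataMatrix.from_array(rng.standard_normal((150, 5)))
        limit = fit_cpca_infinite_alpha(target, background, k=2)
        finite = fit(target, background, alpha=1e8, k=2)
        assert max_principal_angle(limit.components, finite.components) < 1e-3

    def test_full_rank_background_rejected(self, rng):
        background = DataMatrix.from_array(rng.standard_normal((50, 3)))
        target = DataMatrix.from_array(rng.standard_normal((50, 3)))
        with pytest.raises(ValueError, match="finite alpha"):
            fit_cpca_infinite_alpha(target, background, k=1)


class TestVariancePair:
    def setup_method(self):
        self.cov = CovariancePair(np.diag([4.0, 1.0]), np.diag([1.0, 3.0]), 10, 10)

    @pytest.mark.parametrize(
        "v,expected",
        [
            ([1, 0], (4.0, 1.0)),
            ([0, 1], (1.0, 3.0)),
            (np.array([1, 1]) / np.sqrt(2), (2.5, 2.0)),  # hand-evaluated
        ],
    )
    def test_quadratic_form(self, v, expected):
        pair = variance_pair(self.cov, np.asarray(v, dtype=float))
        assert pair.lambda_x == pytest.approx(expected[0])
        assert pair.lambda_y == pytest.approx(expected[1])

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            variance_pair(self.cov, np.array([1.0, 1.0]))


class TestTransform:
    def test_full_rank_projection_is_isometry(self, rng):
        target, background = random_dataset_pair(rng, 40, 40, 5)
        model = fit(target, background, alpha=1.3, k=5)
        projected = transform(target, model)
        centered = target.values - target.values.mean(axis=0)
        np.testing.assert_allclose(
            projected @ projected.T, centered @ centered.T, atol=1e-8
        )

    def test_identity_components_select_centered_columns(self, rng):
        values = rng.standard_normal((12, 4))
        data = DataMatrix.from_array(values)
        model = ContrastiveModel(
            alpha=1.0,
            components=np.eye(4)[:, :2],
            eigenvalues=np.array([2.0, 1.0]),
            k=2,
            mean=values.mean(axis=0),
        )
        np.testing.assert_allclose(
            transform(data, model), values[:, :2] - values[:, :2].mean(axis=0)
        )

    def test_matches_naive_loop_product(self, rng):
        target, background = random_dataset_pair(rng, 15, 15, 4)
        model = fit(target, background, alpha=0.7, k=2)
        got = transform(target, model)
        centered = target.values - model.mean
        expected = np.zeros((15, 2))
        for i in range(15):
            for j in range(2):
                expected[i, j] = sum(
                    centered[i, l] * model.components[l, j] for l in range(4)
                )
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_feature_count_mismatch_rejected(self, rng):
        target, background = random_dataset_pair(rng, 10, 10, 4)
        model = fit(target, background, alpha=1.0, k=2)
        with pytest.raises(ValueError, match="features"):
            transform(DataMatrix.from_array(rng.standard_normal((5, 3))), model)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path, rng):
        target, background = random_dataset_pair(rng, 30, 30, 6)
        for alpha in (2.5, math.inf):
            if math.isinf(alpha):
                # make the background rank-deficient so the limit exists
                background = DataMatrix.from_array(
                    rng.standard_normal((30, 2)) @ rng.standard_normal((2, 6))
                )
            model = fit(target, background, alpha=alpha, k=2)
            path = tmp_path / "model.json"
            model.save(path)
            loaded = ContrastiveModel.load(path)
            assert loaded.alpha == model.alpha
            np.testing.assert_allclose(loaded.components, model.components)
            np.testing.assert_allclose(loaded.mean, model.mean)
            np.testing.assert_allclose(
                transform(target, loaded), transform(target, model)
            )


def test_standardization_scales_by_target_std(rng):
    target, background = random_dataset_pair(rng, 60, 60, 5)
    model = fit(target, background, alpha=1.0, k=2, standardize=True)
    s = target.values.std(axis=0)
    scaled_target = DataMatrix.from_array(target.values / s)
    scaled_background = DataMatrix.from_array(background.values / s)
    ref = fit(scaled_target, scaled_background, alpha=1.0, k=2)
    np.testing.assert_allclose(model.components, ref.components, atol=1e-10)
    np.testing.assert_allclose(
        transform(target, model), transform(scaled_target, ref), atol=1e-10
    )
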