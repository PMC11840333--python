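"""Two-block PLS (canonical and regression modes) and permutation inference."""

import numpy as np
import pytest

from synlink.cohort import (
    BehaviourSpec,
    CohortSpec,
    LatentComponentSpec,
    generate_behaviour_outcomes,
    generate_paired_matrices,
)
from synlink.pls import (
    pearson_with_p,
    permutation_test_pls_ca,
    permutation_test_plsr,
    pls_canonical_fit,
    pls_regression,
)


def angle_grid_max_covariance(X, Y, n_angles=3600):
    """Brute-force oracle for 2-column blocks: maximise |cov(Xw, Yc)| over a
    dense grid of unit weight directions."""
    n = X.shape[0]
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    th = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    WX = np.stack([np.cos(th), np.sin(th)])  # 2 x A
    T = Xs @ WX
    U = Ys @ WX
    cov = T.T @ U / (n - 1)
    return np.abs(cov).max()


class TestCanonicalFit:
    def test_identical_blocks_have_unit_first_correlation(self, rng):
        X = rng.standard_normal((30, 5))
        ca = pls_canonical_fit(X, X.copy(), 2)
        assert ca.correlations[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_angle_grid_oracle_on_two_column_blocks(self, rng):
        X = rng.standard_normal((40, 2))
        Y = X @ rng.standard_normal((2, 2)) + 0.5 * rng.standard_normal((40, 2))
        ca = pls_canonical_fit(X, Y, 1)
        oracle = angle_grid_max_covariance(X, Y)
        assert abs(ca.covariances[0] - oracle) < 1e-5

    def test_planted_single_component_recovered(self):
        spec = CohortSpec(
            n_subjects=5000,
            components=(LatentComponentSpec(0.8),),
            feature_noise_sd=0.01,
            seed=42,
        )
        X, Y, truth = generate_paired_matrices(spec)
        ca = pls_canonical_fit(X, Y, 1)
        assert abs(ca.correlations[0] - 0.8) < 0.02

    def test_scores_orthogonal_within_block(self, rng):
        X = rng.standard_normal((50, 6))
        Y = rng.standard_normal((50, 6))
        ca = pls_canonical_fit(X, Y, 3)
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(ca.x_scores[:, i] @ ca.x_scores[:, j]) < 1e-8
                assert abs(ca.y_scores[:, i] @ ca.y_scores[:, j]) < 1e-8

    def test_weights_unit_norm_and_cov_ordered(self, rng):
        X = rng.standard_normal((50, 6))
        Y = X @ rng.standard_normal((6, 6)) + rng.standard_normal((50, 6))
        ca = pls_canonical_fit(X, Y, 2)
        assert np.allclose(np.linalg.norm(ca.x_weights, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(ca.y_weights, axis=0), 1.0)
        assert ca.covariances[0] >= ca.covariances[1]

    def test_affine_column_rescaling_invariance(self, rng):
        X = rng.standard_normal((40, 4))
        Y = rng.standard_normal((40, 4))
        X2 = X.copy()
        X2[:, 1] = 10.0 * X2[:, 1] - 3.0
        Y2 = Y.copy()
        Y2[:, 2] = -0.2 * Y2[:, 2] + 5.0
        a = pls_canonical_fit(X, Y, 2)
        b = pls_canonical_fit(X2, Y2, 2)
        assert np.allclose(np.abs(a.correlations), np.abs(b.correlations), atol=1e-8)

    def test_zero_variance_column_reported(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 4.0
        with pytest.raises(ValueError, match="zero-variance"):
            pls_canonical_fit(X, rng.standard_normal((20, 3)))

    def test_matches_sklearn_reference(self, rng):
        from sklearn.cross_decomposition import PLSCanonical

        X = rng.standard_normal((30, 5))
        Y = X @ rng.standard_normal((5, 4)) + rng.standard_normal((30, 4))
        ca = pls_canonical_fit(X, Y, 2)
        sk = PLSCanonical(n_components=2, scale=True).fit(X, Y)
        xs, ys = sk.transform(X, Y)
        # both are iterative with ~1e-6 convergence tolerances, so compare
        # at the scale those tolerances imply
        for i in range(2):
            r_sk = abs(np.corrcoef(xs[:, i], ys[:, i])[0, 1])
            assert abs(abs(ca.correlations[i]) - r_sk) < 1e-4
            assert abs(abs(ca.x_weights[:, i] @ sk.x_weights_[:, i]) - 1.0) < 1e-4


class TestPermutationCA:
    def test_strong_signal_gives_zero_p_under_strict_rule(self):
        spec = CohortSpec(n_subjects=200, components=(LatentComponentSpec(0.95),),
                          feature_noise_sd=0.05, seed=3)
        X, Y, _ = generate_paired_matrices(spec)
        res = permutation_test_pls_ca(X, Y, n_components=1, n_permutations=200, seed=5)
        assert res.p_values[0] == 0.0
        smoothed = permutation_test_pls_ca(X, Y, n_components=1, n_permutations=200,
                                           seed=5, smoothed=True)
        assert smoothed.p_values[0] == pytest.approx(1.0 / 201.0)

    def test_seeded_reproducibility(self, rng):
        X = rng.standard_normal((25, 6))
        Y = rng.standard_normal((25, 6))
        a = permutation_test_pls_ca(X, Y, n_permutations=300, seed=11)
        b = permutation_test_pls_ca(X, Y, n_permutations=300, seed=11)
        assert np.array_equal(a.null_distribution, b.null_distribution)
        c = permutation_test_pls_ca(X, Y, n_permutations=1000, seed=12)
        d = permutation_test_pls_ca(X, Y, n_permutations=1000, seed=13)
        assert np.all(np.abs(c.p_values - d.p_values) < 0.03)

    def test_null_length_and_p_range(self, rng):
        X = rng.standard_normal((20, 4))
        Y = rng.standard_normal((20, 4))
        res = permutation_test_pls_ca(X, Y, n_permutations=150, seed=2)
        assert res.null_distribution.shape == (150, 2)
        assert np.all((res.p_values >= 0) & (res.p_values <= 1))


class TestRegression:
    def test_outcome_along_principal_direction_perfectly_fit(self, rng):
        # y proportional to a principal-component score of standardized X is
        # captured exactly by the first PLS component (w ∝ X'y ∝ the same
        # eigenvector of X'X)
        X = rng.standard_normal((60, 4))
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        _, _, vt = np.linalg.svd(Xs, full_matrices=False)
        y = Xs @ vt[0] + 2.0
        fit = pls_regression(X, y, 2)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.rmse == pytest.approx(0.0, abs=1e-6)

    def test_independent_outcome_has_small_r2(self, rng):
        X = rng.standard_normal((1000, 6))
        y = rng.standard_normal(1000)
        fit = pls_regression(X, y, 2)
        assert fit.r_squared < 0.03

    def test_saturated_two_component_fit_equals_ols(self, rng):
        X = rng.standard_normal((30, 2))
        y = X @ np.array([0.7, -1.2]) + rng.standard_normal(30)
        fit = pls_regression(X, y, 2)
        A = np.column_stack([np.ones(30), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose(fit.predictions, A @ beta, atol=1e-10)

    def test_constant_outcome_raises(self, rng):
        with pytest.raises(ValueError, match="constant"):
            pls_regression(rng.standard_normal((10, 3)), np.full(10, 2.0))

    def test_matches_sklearn_reference(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((40, 6))
        y = X @ rng.standard_normal(6) + rng.standard_normal(40)
        fit = pls_regression(X, y, 2)
        sk = PLSRegression(n_components=2).fit(X, y)
        assert np.allclose(fit.predictions, sk.predict(X).ravel(), atol=1e-10)


class TestPermutationR:
    def test_deterministic_outcome_gives_zero_p(self, rng):
        X = rng.standard_normal((100, 4))
        y = X @ np.array([1.0, 0.5, -0.3, 0.8])
        res = permutation_test_plsr(X, y, n_permutations=300, seed=9)
        assert res.p_values[0] == 0.0

    def test_seeded_reproducibility(self, rng):
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        a = permutation_test_plsr(X, y, n_permutations=200, seed=21)
        b = permutation_test_plsr(X, y, n_permutations=200, seed=21)
        assert np.array_equal(a.null_distribution, b.null_distribution)


class TestBehaviouralRecovery:
    def test_planted_r_squared_recovered_in_sample(self):
        spec = CohortSpec(n_subjects=5000, feature_noise_sd=0.01, seed=17,
                          behaviour=BehaviourSpec(target_r_squared=0.45))
        X, _, truth = generate_paired_matrices(spec)
        y = generate_behaviour_outcomes(truth, spec.behaviour)
        fit = pls_regression(X, y, 2)
        assert abs(fit.r_squared - 0.45) < 0.03


class TestPearson:
    def test_perfect_linear_relationships(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_with_p(x, 2 * x + 1)["r"] == pytest.approx(1.0)
        assert pearson_with_p(x, -x)["r"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        out = pearson_with_p(np.array([1, 2, 3, 4]), np.array([1, 3, 2, 4]))
        assert out["r"] == pytest.approx(0.8)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            pearson_with_p(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            pearson_with_p(np.ones(5), np.arange(5.0))
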