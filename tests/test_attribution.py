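import numpy as np
import pytest

from costaware import (
    AttributionMatrix,
    BackgroundSet,
    global_importance,
    linear_attribution,
    masked_score,
    shapley_exact,
    shapley_sampled,
)
from costaware.attribution import attribute_samples, shapley_enumerated


def linear_fn(w):
    w = np.asarray(w, float)
    return lambda X: X @ w


class TestMaskedScore:
    def test_full_subset_is_plain_evaluation(self, rng):
        fn = linear_fn([1.0, -2.0, 0.5])
        bg = BackgroundSet(rng.normal(size=(10, 3)))
        x = np.array([0.3, 1.2, -0.7])
        assert masked_score(fn, x, [0, 1, 2], bg) == pytest.approx(fn(x[None])[0])

    def test_empty_subset_is_background_mean(self):
        bg = BackgroundSet(np.array([[0.0], [1.0]]))
        assert masked_score(lambda X: X[:, 0], [5.0], [], bg) == pytest.approx(0.5)

    def test_linear_model_closed_form(self, rng):
        # masked score of w.x splits into observed part + background-mean part
        w = np.array([2.0, -1.0, 0.5, 3.0])
        bg = BackgroundSet(rng.normal(size=(25, 4)))
        x = rng.normal(size=4)
        S = [0, 2]
        expected = w[S] @ x[S] + w[[1, 3]] @ bg.means[[1, 3]]
        assert masked_score(linear_fn(w), x, S, bg) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        bg = BackgroundSet(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            masked_score(lambda X: X[:, 0], [1.0, 2.0], [], bg)


class TestShapleyExact:
    def test_linear_model(self):
        fn = linear_fn([1.0, 2.0])
        bg = BackgroundSet(np.zeros((1, 2)))
        phi, base = shapley_exact(fn, [1.0, 1.0], bg)
        assert np.allclose(phi, [1.0, 2.0]) and base == 0.0

    def test_product_model_splits_interaction_evenly(self):
        # two orderings of revealing x1, x2 each credit the pair 0 and 1
        fn = lambda X: X[:, 0] * X[:, 1]
        phi, base = shapley_exact(fn, [1.0, 1.0], BackgroundSet(np.zeros((1, 2))))
        assert np.allclose(phi, [0.5, 0.5]) and base == 0.0

    def test_dummy_feature_gets_zero(self, rng):
        fn = lambda X: X[:, 0] + X[:, 1] ** 2
        bg = BackgroundSet(rng.normal(size=(8, 3)))
        phi, _ = shapley_exact(fn, rng.normal(size=3), bg)
        assert phi[2] == pytest.approx(0.0, abs=1e-12)

    def test_local_accuracy_and_symmetry_random_models(self, rng):
        for _ in range(30):
            m = int(rng.integers(2, 6))
            Q = rng.normal(size=(m, m))
            w = rng.normal(size=m)
            fn = lambda X: X @ w + np.einsum("ij,jk,ik->i", X, Q, X)
            bg = BackgroundSet(rng.normal(size=(6, m)))
            x = rng.normal(size=m)
            phi, base = shapley_exact(fn, x, bg)
            assert phi.sum() + base == pytest.approx(float(fn(x[None])[0]), abs=1e-8)
        # symmetry: swap-invariant model, equal coordinates
        fn = lambda X: X[:, 0] * X[:, 1] + X[:, 0] + X[:, 1]
        phi, _ = shapley_exact(fn, [0.7, 0.7], BackgroundSet(np.zeros((1, 2))))
        assert phi[0] == pytest.approx(phi[1])

    def test_matches_full_permutation_enumeration(self, rng):
        fn = lambda X: X[:, 0] * X[:, 1] - 2 * X[:, 2] + X[:, 1] * X[:, 2]
        bg = BackgroundSet(rng.normal(size=(5, 3)))
        x = rng.normal(size=3)
        phi_e, b_e = shapley_exact(fn, x, bg)
        phi_p, b_p = shapley_enumerated(fn, x, bg)
        assert np.allclose(phi_e, phi_p) and b_e == pytest.approx(b_p)

    def test_over_limit_directs_to_sampling(self):
        bg = BackgroundSet(np.zeros((1, 13)))
        with pytest.raises(ValueError, match="shapley_sampled"):
            shapley_exact(lambda X: X.sum(1), np.ones(13), bg)


class TestShapleySampled:
    def test_deterministic_for_fixed_seed(self, rng):
        fn = lambda X: X[:, 0] * X[:, 1]
        bg = BackgroundSet(rng.normal(size=(5, 2)))
        a = shapley_sampled(fn, [1.0, 1.0], bg, 50, seed=7)
        b = shapley_sampled(fn, [1.0, 1.0], bg, 50, seed=7)
        assert np.array_equal(a[0], b[0])

    def test_converges_to_exact(self):
        fn = lambda X: X[:, 0] * X[:, 1]
        bg = BackgroundSet(np.zeros((1, 2)))
        phi, _ = shapley_sampled(fn, [1.0, 1.0], bg, 10_000, seed=0)
        assert np.allclose(phi, [0.5, 0.5], atol=0.05)

    def test_seed_average_within_monte_carlo_error(self, rng):
        # mean over many seeds approaches the exact value at ~3 SE
        fn = lambda X: X[:, 0] * X[:, 1] + 0.5 * X[:, 2]
        bg = BackgroundSet(rng.normal(size=(4, 3)))
        x = rng.normal(size=3)
        exact, _ = shapley_exact(fn, x, bg)
        n_perm, seeds = 20, 50
        draws = np.array([shapley_sampled(fn, x, bg, n_perm, seed=s)[0] for s in range(seeds)])
        se = draws.std(axis=0, ddof=1) / np.sqrt(seeds)
        assert np.all(np.abs(draws.mean(axis=0) - exact) <= 3 * se + 1e-9)


class TestLinearAttribution:
    def test_closed_form(self):
        phi, base = linear_attribution([2.0, -1.0], 0.5, [0.0, 0.0], [1.0, 1.0])
        assert np.allclose(phi, [2.0, -1.0]) and base == pytest.approx(0.5)

    def test_baseline_input_gets_zero(self):
        phi, _ = linear_attribution([3.0, 4.0], 1.0, [0.2, -0.1], [0.2, -0.1])
        assert np.allclose(phi, 0.0)

    def test_equals_exact_shapley_on_random_linear_models(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 9))
            w, b = rng.normal(size=m), float(rng.normal())
            bg = BackgroundSet(rng.normal(size=(7, m)))
            x = rng.normal(size=m)
            fn = lambda X: X @ w + b
            phi_l, base_l = linear_attribution(w, b, bg.means, x)
            phi_e, base_e = shapley_exact(fn, x, bg)
            assert np.allclose(phi_l, phi_e, atol=1e-10)
            assert base_l == pytest.approx(base_e)


class TestGlobalImportance:
    def test_reductions(self):
        A = AttributionMatrix(np.array([[1.0, -2.0], [3.0, 0.0]]), 0.0)
        assert global_importance(A, "mean_abs").tolist() == [2.0, 1.0]
        assert global_importance(A, "sum_abs").tolist() == [4.0, 2.0]
        assert global_importance(AttributionMatrix(np.zeros((3, 2)), 0.0)).tolist() == [0, 0]

    def test_reductions_rank_identically(self, rng):
        A = AttributionMatrix(rng.normal(size=(40, 6)), 0.0)
        a = np.argsort(global_importance(A, "mean_abs"))
        b = np.argsort(global_importance(A, "sum_abs"))
        assert np.array_equal(a, b)

    def test_attribute_samples_local_accuracy(self, rng):
        fn = lambda X: X[:, 0] * X[:, 1] + X[:, 2]
        bg = BackgroundSet(rng.normal(size=(5, 3)))
        X = rng.normal(size=(4, 3))
        A = attribute_samples(fn, X, bg, method="exact")
        assert np.allclose(A.values.sum(axis=1) + A.base_values, fn(X), atol=1e-8)
        df = A.to_frame()
        assert "base_value" in df.columns and df.shape == (4, 4)
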