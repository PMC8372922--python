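"""Likelihood, gradients, fitting, sampling and gauge freedom of the logistic model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmoid.datatypes import (
    BinaryDataset,
    FeatureMatrix,
    FitConfig,
    LatentMatrix,
    ShapeError,
    ValidationError,
)
from sigmoid.model import (
    compute_probabilities,
    embed_samples,
    fit,
    gauge_transform,
    gradients,
    log_likelihood,
    predictive_probability,
    sample_data,
)


class TestComputeProbabilities:
    def test_zero_latents_give_half(self, rng):
        beta = LatentMatrix(np.zeros((4, 2)))
        energies = FeatureMatrix(rng.normal(0, 2, (2, 7)))
        assert np.allclose(compute_probabilities(beta, energies), 0.5)

    def test_closed_form_logistic(self):
        # beta=1, E=ln 3 -> exp(-ln3)/(1+exp(-ln3)) = 1/4
        beta = LatentMatrix(np.ones((2, 1)))
        energies = FeatureMatrix(np.full((1, 3), np.log(3.0)))
        assert np.allclose(compute_probabilities(beta, energies), 0.25)

    def test_matches_scalar_oracle(self, rng):
        beta = LatentMatrix(rng.normal(0, 1, (3, 2)))
        energies = FeatureMatrix(rng.normal(0, 1, (2, 4)))
        pi = compute_probabilities(beta, energies)
        for s in range(3):
            for i in range(4):
                x = sum(beta.values[s, k] * energies.values[k, i] for k in range(2))
                expected = np.exp(-x) / (1 + np.exp(-x))
                assert pi[s, i] == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch(self, rng):
        beta = LatentMatrix(rng.normal(0, 1, (3, 2)))
        energies = FeatureMatrix(rng.normal(0, 1, (3, 4)))
        with pytest.raises(ShapeError):
            compute_probabilities(beta, energies)

    def test_clamping_bounds(self):
        beta = LatentMatrix(np.full((1, 1), 100.0))
        energies = FeatureMatrix(np.full((1, 1), 100.0))
        pi = compute_probabilities(beta, energies, clamp_eps=1e-6)
        assert pi[0, 0] == pytest.approx(1e-6)


class TestLogLikelihood:
    def test_uniform_bernoulli(self, rng):
        data = BinaryDataset((rng.random((2, 3)) < 0.5).astype(int))
        assert log_likelihood(data, np.full((2, 3), 0.5)) == pytest.approx(6 * np.log(0.5))

    def test_perfect_fit_limit(self):
        eps = 1e-9
        data = BinaryDataset(np.array([[0, 1], [1, 0]]))
        probs = np.clip(data.values.astype(float), eps, 1 - eps)
        assert log_likelihood(data, probs) == pytest.approx(4 * np.log(1 - eps))

    def test_double_loop_oracle(self, rng):
        data = BinaryDataset((rng.random((4, 5)) < 0.4).astype(int))
        probs = rng.uniform(0.05, 0.95, (4, 5))
        expected = 0.0
        for s in range(4):
            for i in range(5):
                sig = data.values[s, i]
                expected += sig * np.log(probs[s, i]) + (1 - sig) * np.log(1 - probs[s, i])
        assert log_likelihood(data, probs) == pytest.approx(expected, rel=1e-12)
        assert log_likelihood(data, probs) <= 0


class TestGradients:
    def test_zero_residual_zero_gradient(self, rng, small_model):
        beta, energies = small_model
        pi = compute_probabilities(beta, energies)
        data = BinaryDataset((pi > 2).astype(int))  # all zeros
        grad_b, grad_e = gradients(data, np.zeros_like(pi) + data.values, beta, energies)
        # probs == data exactly -> residual vanishes
        assert np.allclose(grad_b, 0) and np.allclose(grad_e, 0)

    def test_zero_features_kill_latent_gradient(self, rng):
        beta = LatentMatrix(rng.normal(0, 1, (3, 2)))
        energies = FeatureMatrix(np.zeros((2, 5)))
        data = BinaryDataset((rng.random((3, 5)) < 0.5).astype(int))
        pi = compute_probabilities(beta, energies)
        grad_b, _ = gradients(data, pi, beta, energies)
        assert np.allclose(grad_b, 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        S, N, K = rng.integers(2, 7), rng.integers(2, 7), rng.integers(1, 4)
        beta = rng.normal(0, 1, (S, K))
        energies = rng.normal(0, 1, (K, N))
        data = BinaryDataset((rng.random((S, N)) < 0.5).astype(int))

        def L(b, e):
            pi = compute_probabilities(LatentMatrix(b), FeatureMatrix(e))
            return log_likelihood(data, pi)

        pi = compute_probabilities(LatentMatrix(beta), FeatureMatrix(energies))
        grad_b, grad_e = gradients(data, pi, LatentMatrix(beta), FeatureMatrix(energies))
        h = 1e-6
        for arr, grad, which in ((beta, grad_b, "b"), (energies, grad_e, "e")):
            idx = (rng.integers(arr.shape[0]), rng.integers(arr.shape[1]))
            plus, minus = arr.copy(), arr.copy()
            plus[idx] += h
            minus[idx] -= h
            if which == "b":
                fd = (L(plus, energies) - L(minus, energies)) / (2 * h)
            else:
                fd = (L(beta, plus) - L(beta, minus)) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFit:
    def test_constant_data_saturates(self):
        data = BinaryDataset(np.ones((6, 4), dtype=int))
        res = fit(data, FitConfig(K=1, seed=0, max_iters=500))
        assert np.all(np.diff(res.trajectory) >= 0)
        pi = compute_probabilities(res.latents, res.features)
        assert pi.min() > 0.9

    def test_trajectory_monotone_and_final_matches(self, planted_fit):
        assert np.all(np.diff(planted_fit.trajectory) >= -1e-9)
        assert planted_fit.trajectory[-1] == planted_fit.log_likelihood

    def test_planted_recovery(self, planted_bundle, planted_fit):
        pi_true = compute_probabilities(planted_bundle.latents, planted_bundle.features)
        pi_fit = compute_probabilities(planted_fit.latents, planted_fit.features)
        r = np.corrcoef(pi_true.ravel(), pi_fit.ravel())[0, 1]
        assert r > 0.8  # ML recovery sanity floor at these dimensions

    def test_deterministic_given_seed(self, rng):
        data = BinaryDataset((rng.random((20, 8)) < 0.4).astype(int))
        cfg = FitConfig(K=2, seed=42, max_iters=200)
        res1, res2 = fit(data, cfg), fit(data, cfg)
        assert np.array_equal(res1.latents.values, res2.latents.values)
        assert np.array_equal(res1.features.values, res2.features.values)
        assert res1.log_likelihood == res2.log_likelihood

    def test_rejects_bad_K(self, rng):
        with pytest.raises(ValidationError):
            FitConfig(K=0)

    def test_warns_on_overparameterised_K(self, rng):
        data = BinaryDataset((rng.random((4, 4)) < 0.5).astype(int))
        with pytest.warns(UserWarning, match="over-parameterised"):
            fit(data, FitConfig(K=5, seed=0, max_iters=10))


class TestEmbedSamples:
    def test_empty_input_gives_empty_latents(self, small_model):
        _, energies = small_model
        data = BinaryDataset(np.zeros((0, 6), dtype=int), (), energies.variable_ids)
        emb = embed_samples(data, energies, FitConfig(K=2, seed=0))
        assert emb.values.shape == (0, 2)

    def test_unknown_variable_ids_rejected(self, small_model):
        _, energies = small_model
        data = BinaryDataset(np.zeros((2, 6), dtype=int))  # default ids v0..v5 match
        bad = BinaryDataset(np.zeros((2, 6), dtype=int), None, tuple("abcdef"))
        with pytest.raises(ValidationError):
            embed_samples(bad, energies, FitConfig(K=2, seed=0))
        embed_samples(data, energies, FitConfig(K=2, seed=0))  # matching ids pass

    def test_synthetic_recovery_with_known_features(self):
        # gauge freedom prevents comparing beta itself; compare pi
        rng = np.random.default_rng(3)
        beta = LatentMatrix(rng.normal(0, 1, (30, 2)))
        energies = FeatureMatrix(rng.normal(0, 1, (2, 200)))
        data = sample_data(beta, energies, seed=4)
        emb = embed_samples(data, energies, FitConfig(K=2, seed=5, tol=1e-10, max_iters=3000))
        pi_true = compute_probabilities(beta, energies)
        pi_emb = compute_probabilities(emb, energies)
        assert np.mean(np.abs(pi_true - pi_emb)) < 0.05


class TestSampleData:
    def test_empirical_mean_near_half(self, rng):
        beta = LatentMatrix(np.zeros((100, 1)))
        energies = FeatureMatrix(np.zeros((1, 100)))
        data = sample_data(beta, energies, seed=7)
        # 10,000 fair coin flips: 3 SE band with SE = 0.005
        assert abs(data.values.mean() - 0.5) < 0.015

    def test_saturated_probabilities_give_ones(self):
        beta = LatentMatrix(np.full((3, 1), -40.0))
        energies = FeatureMatrix(np.ones((1, 5)))
        assert sample_data(beta, energies, seed=0).values.min() == 1

    def test_seed_determinism(self, small_model):
        beta, energies = small_model
        d1 = sample_data(beta, energies, seed=9)
        d2 = sample_data(beta, energies, seed=9)
        assert np.array_equal(d1.values, d2.values)


class TestPredictiveProbability:
    def test_single_sample_is_bernoulli_product(self, rng):
        beta = LatentMatrix(rng.normal(0, 1, (1, 2)))
        energies = FeatureMatrix(rng.normal(0, 1, (2, 4)))
        pi = compute_probabilities(beta, energies)[0]
        sigma = np.array([1, 0, 1, 1])
        expected = np.prod(pi**sigma * (1 - pi) ** (1 - sigma))
        assert predictive_probability(sigma, beta, energies) == pytest.approx(expected, rel=1e-12)

    def test_uniform_model_gives_two_to_minus_N(self):
        beta = LatentMatrix(np.zeros((5, 1)))
        energies = FeatureMatrix(np.zeros((1, 6)))
        assert predictive_probability(np.ones(6, dtype=int), beta, energies) == pytest.approx(
            2.0**-6, rel=1e-12
        )

    def test_sums_to_one_over_all_configurations(self, small_model):
        beta, energies = small_model
        N = energies.n_variables
        total = sum(
            predictive_probability(
                np.array([(m >> (N - 1 - b)) & 1 for b in range(N)]), beta, energies
            )
            for m in range(2**N)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_rejects_non_binary_configuration(self, small_model):
        beta, energies = small_model
        with pytest.raises(ValidationError):
            predictive_probability(np.array([0, 1, 2, 0, 1, 0]), beta, energies)


class TestGaugeTransform:
    def test_identity_leaves_parameters(self, small_model):
        beta, energies = small_model
        b2, e2 = gauge_transform(beta, energies, np.eye(2))
        assert np.allclose(b2.values, beta.values)
        assert np.allclose(e2.values, energies.values)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_predictions_invariant(self, seed):
        rng = np.random.default_rng(seed)
        beta = LatentMatrix(rng.normal(0, 1, (4, 3)))
        energies = FeatureMatrix(rng.normal(0, 1, (3, 5)))
        M = rng.normal(0, 1, (3, 3)) + 3 * np.eye(3)  # well-conditioned
        b2, e2 = gauge_transform(beta, energies, M)
        pi1 = compute_probabilities(beta, energies)
        pi2 = compute_probabilities(b2, e2)
        assert np.abs(pi1 - pi2).max() < 1e-8

    def test_singular_matrix_rejected(self, small_model):
        beta, energies = small_model
        with pytest.raises(ValidationError):
            gauge_transform(beta, energies, np.zeros((2, 2)))
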