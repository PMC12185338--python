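"""Variational embedding model: likelihood, objective, pruning, training."""

import math

import numpy as np
import pytest

from repalign import (PointEmbedding, PriorSpec, TrainConfig, Triplet, VICE,
                      VariationalEmbedding, elbo_loss, point_estimate,
                      posterior_prob_positive, prune_dimensions,
                      sample_weights, triplet_choice_probs)
from repalign.model import complexity_term
from repalign.synthetic import GroundTruth, generate_embedding, simulate_dataset


class TestChoiceProbs:
    def test_identical_rows_uniform(self):
        Y = np.ones((3, 4))
        np.testing.assert_allclose(triplet_choice_probs(Y, (0, 1, 2)),
                                   [1 / 3, 1 / 3, 1 / 3])

    def test_log2_logits(self):
        # dot products (ln 2, 0, 0) -> softmax (0.5, 0.25, 0.25)
        a = math.sqrt(math.log(2))
        Y = np.array([[a, 0], [a, 0], [0, 0.0]])
        np.testing.assert_allclose(triplet_choice_probs(Y, (0, 1, 2)),
                                   [0.5, 0.25, 0.25])

    def test_probs_sum_to_one_and_permute(self, rng):
        Y = rng.exponential(size=(6, 3))
        p = triplet_choice_probs(Y, (0, 2, 4))
        assert p.sum() == pytest.approx(1.0)
        # swapping j and k swaps the (i,j)/(i,k) slots
        q = triplet_choice_probs(Y, (0, 4, 2))
        np.testing.assert_allclose(q, p[[1, 0, 2]])

    def test_shift_invariance(self):
        # appending a shared constant feature adds c to all three dots
        Y = np.array([[1, 0.5], [0.2, 1], [0.7, 0.1]])
        Yc = np.hstack([Y, np.full((3, 1), 2.0)])
        np.testing.assert_allclose(triplet_choice_probs(Yc, (0, 1, 2)),
                                   triplet_choice_probs(Y, (0, 1, 2)))


class TestSampleWeights:
    def test_degenerate_sigma_returns_rectified_mu(self, rng):
        mu = rng.normal(size=(5, 3))
        emb = VariationalEmbedding(mu, np.full((5, 3), 1e-12))
        np.testing.assert_allclose(sample_weights(emb, 0),
                                   np.maximum(mu, 0), atol=1e-9)

    def test_determinism(self, rng):
        emb = VariationalEmbedding(rng.normal(size=(4, 2)),
                                   np.full((4, 2), 0.5))
        np.testing.assert_array_equal(sample_weights(emb, 42),
                                      sample_weights(emb, 42))

    def test_monte_carlo_mean(self):
        mu = np.array([[0.3, -0.2]])
        sigma = np.array([[0.7, 1.1]])
        emb = VariationalEmbedding(mu, sigma)
        n = 100_000
        rng = np.random.default_rng(9)
        draws = mu + sigma * rng.standard_normal((n, 1, 2))
        se = sigma / math.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 4 * se)


class TestObjective:
    def test_kl_zero_for_matched_single_gaussian(self):
        prior = PriorSpec(pi=0.5, sigma_spike=0.8, sigma_slab=0.8)
        emb = VariationalEmbedding(np.zeros((6, 4)), np.full((6, 4), 0.8))
        assert complexity_term(emb, prior, method="exact") == pytest.approx(0.0)

    def test_nll_ln3_for_uniform_choices(self):
        # identical rows with zero sigma: every pair has probability 1/3
        emb = VariationalEmbedding(np.ones((5, 2)), np.full((5, 2), 1e-12))
        data = simulate_dataset(
            GroundTruth(generate_embedding(5, 2, 0.0, seed=3), seed=3),
            50, "softmax", seed=3)
        prior = PriorSpec(sigma_spike=1.0, sigma_slab=1.0)
        loss = elbo_loss(emb, prior, data, n_total=10 ** 12, seed=0)
        assert loss == pytest.approx(math.log(3), abs=1e-6)

    def test_mc_kl_matches_closed_form(self):
        """Monte-Carlo estimator against the closed-form Gaussian KL."""
        prior = PriorSpec(pi=0.5, sigma_spike=0.6, sigma_slab=0.6)
        rng = np.random.default_rng(4)
        emb = VariationalEmbedding(rng.normal(size=(3, 2)),
                                   np.full((3, 2), 0.4))
        exact = complexity_term(emb, prior, method="exact")
        n = 100_000
        est = complexity_term(emb, prior, np.random.default_rng(8),
                              n_samples=n, method="hybrid")
        # per-sample sd of -log p at the sampled W, conservative bound
        assert est == pytest.approx(exact, abs=0.05 * abs(exact) + 0.05)

    def test_estimators_agree_in_expectation(self):
        prior = PriorSpec()
        rng = np.random.default_rng(5)
        emb = VariationalEmbedding(rng.normal(size=(4, 3)),
                                   np.abs(rng.normal(0.5, 0.1, (4, 3))))
        hybrid = complexity_term(emb, prior, np.random.default_rng(1),
                                 n_samples=20_000, method="hybrid")
        mc = complexity_term(emb, prior, np.random.default_rng(2),
                             n_samples=20_000, method="mc")
        assert mc == pytest.approx(hybrid, rel=0.05, abs=0.5)

    def test_empty_batch_raises(self):
        emb = VariationalEmbedding(np.ones((4, 2)), np.ones((4, 2)))
        from repalign import TripletDataset
        empty = TripletDataset(np.empty((0, 3)), np.empty(0), m=4)
        with pytest.raises(ValueError):
            elbo_loss(emb, PriorSpec(), empty, n_total=10)


class TestPosteriorAndPruning:
    def test_prob_positive_values(self):
        mu = np.array([[0.0, 1.6449, -1.6449]])
        sigma = np.ones((1, 3))
        p = posterior_prob_positive(VariationalEmbedding(mu, sigma))
        np.testing.assert_allclose(p[0], [0.5, 0.95, 0.05], atol=1e-4)

    def test_prune_negative_dimension(self):
        mu = np.column_stack([np.full(10, -5.0), np.full(10, 5.0)])
        emb = VariationalEmbedding(mu, np.full((10, 2), 0.5))
        pruned = prune_dimensions(emb)
        assert pruned.active_dims == [1]

    def test_prune_boundary_and_idempotence(self):
        # dim 0: exactly 5 supporting objects -> kept; dim 1: 4 -> pruned
        mu = np.zeros((10, 2))
        mu[:5, 0] = 10.0
        mu[:4, 1] = 10.0
        emb = VariationalEmbedding(mu, np.full((10, 2), 0.5))
        pruned = prune_dimensions(emb, threshold=0.05, min_objects=5)
        assert pruned.active_dims == [0]
        again = prune_dimensions(pruned, threshold=0.05, min_objects=5)
        assert again.active_dims == pruned.active_dims

    def test_prune_to_nothing_raises(self):
        emb = VariationalEmbedding(np.full((8, 3), -4.0), np.full((8, 3), 0.5))
        with pytest.raises(ValueError):
            prune_dimensions(emb)

    def test_exact_support_rule(self):
        """3 of 10 dims have >= 5 objects at Pr(w>0) >= 0.95; only those stay."""
        rng = np.random.default_rng(0)
        m, p = 20, 10
        sigma = np.full((m, p), 1.0)
        mu = np.full((m, p), -3.0)  # Pr ~ 0.001 everywhere
        strong = [2, 5, 7]
        for j in strong:
            mu[:6, j] = 3.0  # 6 objects with Pr ~ 0.999
        for j in [0, 4]:
            mu[:4, j] = 3.0  # only 4 supporters: below min_objects
        emb = VariationalEmbedding(mu, sigma)
        assert prune_dimensions(emb).active_dims == strong


class TestPointEstimate:
    def test_rectification_and_ordering(self):
        mu = np.array([[1.0, -1.0, 2.0],
                       [2.0, -2.0, 7.0]])
        emb = VariationalEmbedding(mu, np.full((2, 3), 0.5))
        pe = point_estimate(emb)
        # column sums after rectification: (3, 0, 9) -> order dim2, dim0, dim1
        assert pe.dim_ids == ["dim_2", "dim_0", "dim_1"]
        np.testing.assert_allclose(pe.values[:, 0], [2.0, 7.0])
        np.testing.assert_allclose(pe.values[:, 2], [0.0, 0.0])
        assert (pe.values >= 0).all()

    def test_restricted_to_active(self):
        mu = np.ones((4, 3))
        emb = VariationalEmbedding(mu, np.full((4, 3), 0.5),
                                   active_dims=[0, 2])
        assert point_estimate(emb).k == 2


@pytest.fixture(scope="module")
def tiny_data():
    truth = generate_embedding(15, 3, 0.4, seed=0)
    return simulate_dataset(GroundTruth(truth, seed=0), 2000, "argmax", seed=0)


class TestTraining:
    def test_zero_epochs_returns_init(self, tiny_data):
        cfg = TrainConfig(p_init=5, max_epochs=0, seed=3)
        res = VICE(tiny_data, cfg).fit()
        assert res.n_epochs == 0
        assert res.embedding.p == 5
        assert res.embedding.active_dims == list(range(5))
        np.testing.assert_allclose(res.embedding.sigma, 0.5)

    def test_determinism(self, tiny_data):
        cfg = TrainConfig(p_init=5, max_epochs=5, prune_interval=0, seed=7)
        a = VICE(tiny_data, cfg).fit()
        b = VICE(tiny_data, cfg).fit()
        np.testing.assert_array_equal(a.embedding.mu, b.embedding.mu)
        np.testing.assert_array_equal(a.embedding.sigma, b.embedding.sigma)

    def test_training_reduces_loss_and_beats_chance(self, tiny_data):
        cfg = TrainConfig(p_init=6, max_epochs=60, prune_interval=0,
                          stability_epochs=100, seed=1)
        res = VICE(tiny_data, cfg).fit()
        assert res.history["nll"].iloc[-1] < res.history["nll"].iloc[0]
        assert res.accuracy(tiny_data) > 1 / 3 + 0.1
        assert res.n_dims <= 6

    def test_summary_mentions_dimensions(self, tiny_data):
        cfg = TrainConfig(p_init=4, max_epochs=3, prune_interval=0, seed=0)
        text = VICE(tiny_data, cfg).fit().summary()
        assert "retained dimensions" in text
        assert "dim_" in text
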