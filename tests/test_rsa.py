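"""Choice-probability RSMs, dimension matching and cumulative analyses."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from repalign import (PointEmbedding, RSM, cumulative_rsa, dims_needed,
                      explainable_variance, match_dimensions, rsm_correlation,
                      rsm_from_embedding)


def naive_rsm(Y):
    """Triple-loop oracle for the context-averaged choice probability."""
    m = Y.shape[0]
    S = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            vals = []
            for k in range(m):
                if k in (i, j):
                    continue
                eij = math.exp(Y[i] @ Y[j])
                eik = math.exp(Y[i] @ Y[k])
                ejk = math.exp(Y[j] @ Y[k])
                vals.append(eij / (eij + eik + ejk))
            S[i, j] = sum(vals) / len(vals)
    return S


def cluster_embedding(m, rng):
    """Embedding with three strong disjoint cluster dims and weak noise dims."""
    vals = 0.05 * rng.random((m, 8))
    third = m // 4
    vals[:third, 0] += 1.5
    vals[third:2 * third, 1] += 1.5
    vals[2 * third:3 * third, 2] += 1.5
    return PointEmbedding(vals)


class TestRSMConstruction:
    def test_identical_rows_give_one_third(self):
        Y = PointEmbedding(np.ones((6, 3)))
        S = rsm_from_embedding(Y).values
        off = S[~np.eye(6, dtype=bool)]
        np.testing.assert_allclose(off, 1 / 3)
        np.testing.assert_allclose(np.diag(S), 1.0)

    def test_three_objects_single_context(self):
        a = math.sqrt(math.log(2))
        Y = PointEmbedding(np.array([[a, 0], [a, 0], [0, 0.0]]))
        S = rsm_from_embedding(Y).values
        assert S[0, 1] == pytest.approx(0.5)
        assert S[0, 2] == pytest.approx(0.25)

    def test_matches_naive_oracle(self, embedding_12x5):
        S = rsm_from_embedding(embedding_12x5).values
        np.testing.assert_allclose(S, naive_rsm(embedding_12x5.values),
                                   atol=1e-12)

    def test_entries_in_open_unit_interval(self, embedding_12x5):
        S = rsm_from_embedding(embedding_12x5).values
        off = S[~np.eye(12, dtype=bool)]
        assert ((off > 0) & (off < 1)).all()
        np.testing.assert_allclose(S, S.T)

    def test_column_permutation_invariance(self, embedding_12x5):
        perm = [4, 2, 0, 1, 3]
        S1 = rsm_from_embedding(embedding_12x5).values
        S2 = rsm_from_embedding(
            PointEmbedding(embedding_12x5.values[:, perm])).values
        np.testing.assert_allclose(S1, S2)

    def test_sampled_contexts_converge(self, rng):
        Y = PointEmbedding(rng.exponential(0.5, size=(30, 4)))
        exact = rsm_from_embedding(Y, "all").values
        approx = rsm_from_embedding(Y, "sampled", n_ctx=2000, seed=0).values
        assert np.abs(exact - approx).max() < 0.03

    def test_too_few_objects(self):
        with pytest.raises(ValueError):
            rsm_from_embedding(PointEmbedding(np.ones((2, 2))))


class TestRSMCorrelation:
    def test_identity_and_affine(self, embedding_12x5):
        A = rsm_from_embedding(embedding_12x5)
        assert rsm_correlation(A, A) == pytest.approx(1.0)
        B = RSM(0.2 + 0.5 * A.values - np.diag(np.diag(0.2 + 0.5 * A.values))
                + np.eye(12))
        assert rsm_correlation(A, B) == pytest.approx(1.0)

    def test_hand_computed_four_objects(self):
        a = np.array([[1, .2, .3, .4], [.2, 1, .5, .6],
                      [.3, .5, 1, .7], [.4, .6, .7, 1.0]])
        b = np.array([[1, .3, .1, .5], [.3, 1, .4, .2],
                      [.1, .4, 1, .6], [.5, .2, .6, 1.0]])
        iu = np.triu_indices(4, 1)
        expected = stats.pearsonr(a[iu], b[iu])[0]
        assert rsm_correlation(RSM(a), RSM(b)) == pytest.approx(expected)

    def test_zero_variance_raises(self):
        flat = RSM(np.full((4, 4), 0.3) + 0.7 * np.eye(4))
        other = RSM(np.eye(4))
        with pytest.raises(ValueError):
            rsm_correlation(flat, other)


class TestMatchDimensions:
    def test_permutation_recovered(self, rng):
        A = PointEmbedding(rng.exponential(size=(25, 4)))
        perm = [2, 0, 3, 1]
        B = PointEmbedding(A.values[:, perm])
        match = match_dimensions(A, B, unique=True)
        np.testing.assert_allclose(match.correlations, 1.0)
        recovered = dict(zip(match.source_dims, match.target_dims))
        assert recovered == {a: perm.index(a) for a in range(4)}

    def test_replacement_contrast(self, rng):
        A = PointEmbedding(rng.exponential(size=(30, 2)))
        # B duplicates A's first column
        B = PointEmbedding(np.column_stack([A.values[:, 0], A.values[:, 0]]))
        with_rep = match_dimensions(A, B, unique=False)
        assert with_rep.target_dims.count(0) + with_rep.target_dims.count(1) == 2
        unique = match_dimensions(A, B, unique=True)
        assert sorted(unique.target_dims) == [0, 1]

    def test_greedy_equals_exhaustive_on_small_instance(self, rng):
        A = PointEmbedding(rng.random((6, 4)))
        B = PointEmbedding(rng.random((6, 5)))
        greedy = match_dimensions(A, B, unique=True)
        # exhaustive: lexicographically best sorted |r| sequence over
        # injective assignments
        C = np.corrcoef(A.values.T, B.values.T)[:4, 4:]
        best_seq, best_assign = None, None
        for targets in itertools.permutations(range(5), 4):
            seq = tuple(sorted((abs(C[a, b]) for a, b in enumerate(targets)),
                               reverse=True))
            if best_seq is None or seq > best_seq:
                best_seq, best_assign = seq, targets
        got = tuple(sorted(np.abs(greedy.correlations), reverse=True))
        np.testing.assert_allclose(got, best_seq, atol=1e-12)

    def test_unique_never_beats_replacement(self, rng):
        A = PointEmbedding(rng.random((20, 6)))
        B = PointEmbedding(rng.random((20, 4)))
        rep = {a: abs(r) for a, _, r in
               match_dimensions(A, B, unique=False).pairs}
        for a, _, r in match_dimensions(A, B, unique=True).pairs:
            assert abs(r) <= rep[a] + 1e-12


class TestCumulativeRSA:
    def test_full_prefix_equals_direct_correlation(self, embedding_12x5, rng):
        ref = rsm_from_embedding(
            PointEmbedding(rng.exponential(size=(12, 3))))
        ranking = list(range(5))
        rs = cumulative_rsa(embedding_12x5, ref, ranking)
        direct = rsm_correlation(rsm_from_embedding(embedding_12x5), ref)
        assert rs[-1] == pytest.approx(direct, abs=1e-12)

    def test_reference_from_top_dimension(self, rng):
        Y = PointEmbedding(rng.exponential(size=(15, 4)))
        ref = rsm_from_embedding(Y.subset([2]))
        rs = cumulative_rsa(Y, ref, [2, 0, 1, 3])
        assert rs[0] == pytest.approx(1.0)
        assert dims_needed(Y, ref, [2, 0, 1, 3], 0.95) == 1

    def test_planted_three_dimension_reference(self, rng):
        # three strong object-disjoint cluster dimensions plus weak noise:
        # each of the first three prefixes adds an indispensable cluster
        m = 40
        Y = cluster_embedding(m, rng)
        ranking = list(range(8))
        ref = rsm_from_embedding(Y.subset(ranking[:3]))
        assert dims_needed(Y, ref, ranking, 0.999) == 3


class TestExplainableVariance:
    def test_arithmetic(self):
        assert explainable_variance(math.sqrt(0.8), 0.8) == pytest.approx(1.0)
        assert explainable_variance(0.0, 0.5) == 0.0
        assert explainable_variance(math.sqrt(0.5), 0.8) == pytest.approx(0.625)

    def test_ceiling_validation(self):
        with pytest.raises(ValueError):
            explainable_variance(0.5, 0.0)
        with pytest.warns(UserWarning):
            assert explainable_variance(1.0, 0.5) > 1
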