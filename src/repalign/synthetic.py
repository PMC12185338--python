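"""Synthetic ground truth: planted embeddings, features and choice data.

These generators produce the statistical structure the framework assumes
— a sparse non-negative object embedding, a feature matrix whose
dot-product geometry mirrors it, and triplet choices resolved from it
either deterministically (argmax) or stochastically (softmax) — so every
stage of the pipeline can be exercised and validated by parameter
recovery without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix, rectify
from .model import PointEmbedding
from .triplets import ODD_SLOT, TripletDataset, sample_triplets, simulate_choices

__all__ = ["GroundTruth", "generate_embedding", "generate_features",
           "simulate_dataset", "recovery_report"]


@dataclass
class GroundTruth:
    """A planted embedding plus the generative settings that produced it."""

    embedding: PointEmbedding
    loading: np.ndarray | None = None  # (d, k) non-negative
    noise_sd: float = 0.1
    seed: int = 0


def generate_embedding(m: int, k: int, sparsity: float = 0.6,
                       scale: float = 1.0, seed: int = 0,
                       max_resample: int = 100) -> PointEmbedding:
    """Sparse non-negative planted embedding.

    Entries are zero with probability ``sparsity`` and otherwise drawn
    exponential with mean ``scale`` (a heavy right tail, as in learned
    sparse positive similarity embeddings). All-zero columns are resampled
    so every dimension carries signal; infeasible settings raise after
    ``max_resample`` attempts.
    """
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    def draw() -> np.ndarray:
        mask = rng.random((m, k)) >= sparsity
        return mask * rng.exponential(scale, size=(m, k))

    vals = draw()
    for _ in range(max_resample):
        empty = ~vals.any(axis=0)
        if not empty.any():
            break
        vals[:, empty] = draw()[:, empty]
    else:
        raise ValueError("could not produce non-empty columns; "
                         "sparsity too high for this m")
    return PointEmbedding(vals)


def generate_features(truth: GroundTruth, d: int,
                      seed: int | None = None) -> FeatureMatrix:
    """Feature matrix whose dot-product structure mirrors the embedding.

    features = embedding @ loading.T + Gaussian noise, rectified. The
    loading is non-negative (rectified-normal by default) so feature-space
    similarity reflects embedding-space similarity; with an orthogonal
    loading and zero noise the two induce identical choices.
    """
    emb = truth.embedding.values
    k = emb.shape[1]
    if d < k:
        raise ValueError("d must be >= the embedding dimensionality")
    if d < 2 * k:
        import warnings
        warnings.warn("d < 2k: feature space may lose embedding structure")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if truth.loading is None:
        loading = np.abs(rng.standard_normal((d, k)))
    else:
        loading = np.asarray(truth.loading, dtype=float)
        if loading.shape != (d, k):
            raise ValueError("loading must have shape (d, k)")
        if (loading < 0).any():
            raise ValueError("loading must be non-negative")
    vals = emb @ loading.T + truth.noise_sd * rng.standard_normal((emb.shape[0], d))
    return rectify(FeatureMatrix(vals, list(truth.embedding.object_ids)))


def simulate_dataset(truth: GroundTruth, n: int, mode: str = "argmax",
                     temperature: float = 1.0, seed: int = 0
                     ) -> TripletDataset:
    """Sample triplets and resolve choices from the planted embedding.

    ``argmax`` picks the most similar pair deterministically (the
    simulated-observer rule); ``softmax`` samples the pair from the
    three-way softmax of dot products divided by ``temperature``,
    emulating stochastic choices consistent with the model likelihood
    (temperature 1) and converging to argmax as temperature -> 0.
    """
    trips = sample_triplets(truth.embedding.m, n, seed)
    feats = FeatureMatrix(truth.embedding.values,
                          list(truth.embedding.object_ids))
    if mode == "argmax":
        return simulate_choices(feats, trips)
    if mode != "softmax":
        raise ValueError("mode must be 'argmax' or 'softmax'")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed + 1)
    X = truth.embedding.values
    xi, xj, xk = X[trips[:, 0]], X[trips[:, 1]], X[trips[:, 2]]
    logits = np.stack([(xi * xj).sum(1), (xi * xk).sum(1), (xj * xk).sum(1)],
                      axis=1) / temperature
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(trips))
    cls = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    odd = trips[np.arange(len(trips)), np.asarray(ODD_SLOT)[cls]]
    return TripletDataset(trips, odd, truth.embedding.m)


def recovery_report(truth: PointEmbedding,
                    estimate: PointEmbedding) -> dict[str, float]:
    """Greedy unique dimension matching between truth and estimate.

    Returns min/median/mean matched Pearson r and the dimensionality
    difference (estimate minus truth) — the standard summary of a
    parameter-recovery experiment.
    """
    from .rsa import match_dimensions

    match = match_dimensions(truth, estimate, unique=True)
    rs = match.correlations
    return {
        "min_r": float(np.min(rs)) if len(rs) else float("nan"),
        "median_r": float(np.median(rs)) if len(rs) else float("nan"),
        "mean_r": float(np.mean(rs)) if len(rs) else float("nan"),
        "n_matched": int(len(rs)),
        "dim_difference": int(estimate.k - truth.k),
    }
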