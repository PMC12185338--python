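"""Jackknife relevance of embedding dimensions for individual choices.

For one triplet, the model's predicted odd-one-out follows from the
softmax over pairwise dot products of the full embedding. Removing one
dimension at a time and recording the change in the predicted pair's
probability yields a per-dimension relevance score for that trial;
aggregated over many trials and combined with human labels of what each
dimension encodes (semantic, visual, ...) this localizes which kinds of
dimensions drive behaviour, and where two systems' choices diverge.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PointEmbedding
from .triplets import PAIR_SLOTS, Triplet

__all__ = ["RelevanceProfile", "LabelledAggregate", "dimension_relevance",
           "most_relevant_dimension", "aggregate_relevance",
           "divergent_triplets"]


@dataclass
class RelevanceProfile:
    """Per-dimension jackknife relevance for one triplet.

    ``base_probs`` are the full-embedding probabilities over the pairs
    ((i,j), (i,k), (j,k)); ``delta[d]`` is the drop in the predicted
    pair's probability when dimension d is zeroed out (positive when the
    dimension supported the prediction).
    """

    triplet: Triplet
    base_probs: np.ndarray
    predicted_pair_slot: int
    delta: np.ndarray

    @property
    def top_dim(self) -> int:
        return most_relevant_dimension(self)

    @property
    def predicted_pair(self) -> tuple[int, int]:
        a, b = PAIR_SLOTS[self.predicted_pair_slot]
        return (self.triplet[a], self.triplet[b])

    @property
    def p_full(self) -> float:
        return float(self.base_probs[self.predicted_pair_slot])


@dataclass
class LabelledAggregate:
    """Counts of top-dimension label categories over a triplet sample."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()} if t else {}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.counts.items()),
                            columns=["category", "count"])


def _pair_probs(rows: np.ndarray) -> np.ndarray:
    logits = np.array([rows[0] @ rows[1], rows[0] @ rows[2],
                       rows[1] @ rows[2]])
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def dimension_relevance(Y: PointEmbedding, t: Triplet) -> RelevanceProfile:
    """Jackknife each dimension out and record the probability change.

    The tracked probability is that of the pair predicted most similar
    under the full embedding (equivalently, the odd-one-out
    identification); delta_d = p_full - p_without_d.
    """
    t = Triplet.of(*t)
    rows = Y.values[list(t)]
    base = _pair_probs(rows)
    slot = int(base.argmax())  # ties: lowest pair slot
    p_full = base[slot]
    k = Y.k
    delta = np.empty(k)
    for d in range(k):
        sub = np.delete(rows, d, axis=1)
        delta[d] = p_full - _pair_probs(sub)[slot]
    return RelevanceProfile(t, base, slot, delta)


def most_relevant_dimension(profile: RelevanceProfile) -> int:
    """Index with maximal |delta|; ties resolve to the lowest index."""
    return int(np.argmax(np.abs(profile.delta)))


def aggregate_relevance(Y: PointEmbedding, triplets: np.ndarray,
                        dim_labels: dict[int, str] | list[str]
                        ) -> LabelledAggregate:
    """Count top-dimension label categories over a sample of triplets.

    ``dim_labels`` maps each active dimension index to a category such as
    ``semantic``, ``visual``, ``mixed`` or ``unclear``; every dimension
    must be labelled.
    """
    if not isinstance(dim_labels, dict):
        dim_labels = dict(enumerate(dim_labels))
    missing = [d for d in range(Y.k) if d not in dim_labels]
    if missing:
        raise ValueError(f"unlabelled dimensions: {missing}")
    counts: Counter[str] = Counter()
    for trip in np.asarray(triplets, dtype=np.int64).reshape(-1, 3):
        prof = dimension_relevance(Y, Triplet.of(*trip))
        counts[dim_labels[prof.top_dim]] += 1
    return LabelledAggregate(dict(counts))


def divergent_triplets(Y_a: PointEmbedding, Y_b: PointEmbedding,
                       triplets: np.ndarray, top_n: int = 10
                       ) -> list[tuple[float, RelevanceProfile,
                                       RelevanceProfile]]:
    """Rank triplets by how strongly the two embeddings' choices diverge.

    The divergence score is zero when both embeddings predict the same
    most-similar pair, and otherwise the mean of the two models'
    confidences in their own (conflicting) predictions — maximal when both
    are certain and disagree. Returns the ``top_n`` highest-scoring
    triplets with both relevance profiles attached, sorted descending.
    """
    if Y_a.object_ids != Y_b.object_ids:
        raise ValueError("embeddings must cover the same objects")
    scored = []
    for trip in np.asarray(triplets, dtype=np.int64).reshape(-1, 3):
        t = Triplet.of(*trip)
        pa = dimension_relevance(Y_a, t)
        pb = dimension_relevance(Y_b, t)
        disagree = pa.predicted_pair_slot != pb.predicted_pair_slot
        score = 0.5 * (pa.p_full + pb.p_full) if disagree else 0.0
        scored.append((float(score), pa, pb))
    scored.sort(key=lambda s: -s[0])
    return scored[:top_n]


def export_relevance(Y: PointEmbedding, triplets: np.ndarray,
                     path: str | Path) -> pd.DataFrame:
    """Tab-separated per-triplet relevance: i j k top_dim delta_top p_full."""
    rows = []
    for trip in np.asarray(triplets, dtype=np.int64).reshape(-1, 3):
        prof = dimension_relevance(Y, Triplet.of(*trip))
        rows.append((*prof.triplet, prof.top_dim,
                     prof.delta[prof.top_dim], prof.p_full))
    df = pd.DataFrame(rows, columns=["i", "j", "k", "top_dim", "delta_top",
                                     "p_full"])
    df.to_csv(path, sep="\t", index=False)
    return df
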