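"""Representational similarity analysis on choice-probability matrices.

The similarity of two objects is defined behaviourally: the probability
that they are judged the most similar pair when shown together with a
third context object, averaged over all (or a sample of) contexts. This
turns any non-negative embedding into an m x m representational
similarity matrix (RSM) on a common probability scale, enabling direct
correlation between embeddings from different sources (e.g. human
behaviour vs a network's features), dimension-by-dimension matching, and
cumulative analyses of how many dimensions of one system are needed to
reproduce the similarity structure of another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import PointEmbedding

__all__ = ["RSM", "rsm_from_embedding", "rsm_correlation",
           "DimensionMatch", "match_dimensions", "cumulative_rsa",
           "dims_needed", "explainable_variance"]


@dataclass
class RSM:
    """Symmetric m x m matrix of context-averaged choice probabilities."""

    values: np.ndarray
    object_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("RSM must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("RSM must be symmetric")
        if self.object_ids is None:
            self.object_ids = [f"obj_{i}" for i in range(self.m)]

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.m, k=1)
        return self.values[iu]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".npz":
            np.savez(path, rsm=self.values,
                     object_ids=np.asarray(self.object_ids))
        else:
            pd.DataFrame(self.values, index=self.object_ids,
                         columns=self.object_ids).to_csv(
                path, sep="\t", index_label="object_id")

    @classmethod
    def load(cls, path: str | Path) -> "RSM":
        path = Path(path)
        if path.suffix == ".npz":
            with np.load(path, allow_pickle=False) as data:
                return cls(data["rsm"], [str(x) for x in data["object_ids"]])
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(i) for i in df.index])


def rsm_from_embedding(Y: PointEmbedding | np.ndarray,
                       context: str = "all",
                       n_ctx: int = 1000,
                       seed: int = 0) -> RSM:
    """Choice-probability RSM from a non-negative embedding.

    S_ij is the probability that (i, j) is picked as the most similar pair
    in a triplet with context object k, under the softmax over pairwise
    dot products, averaged over contexts k not in {i, j}. ``context="all"``
    enumerates every context exactly (O(m^3), vectorized); ``"sampled"``
    averages over ``n_ctx`` uniformly drawn contexts per pair, which is the
    practical choice for m in the hundreds and beyond.
    """
    vals = Y.values if isinstance(Y, PointEmbedding) else np.asarray(Y, float)
    ids = Y.object_ids if isinstance(Y, PointEmbedding) else None
    m = vals.shape[0]
    if m < 3:
        raise ValueError("need at least 3 objects to form a context")
    L = vals @ vals.T  # pairwise dot-product logits
    S = np.zeros((m, m))
    rng = np.random.default_rng(seed)
    for i in range(m):
        for j in range(i + 1, m):
            if context == "all":
                ks = np.array([k for k in range(m) if k != i and k != j])
            elif context == "sampled":
                pool = np.array([k for k in range(m) if k != i and k != j])
                ks = rng.choice(pool, size=n_ctx, replace=True)
            else:
                raise ValueError("context must be 'all' or 'sampled'")
            a = L[i, j]
            b = L[i, ks]
            c = L[j, ks]
            mx = np.maximum(a, np.maximum(b, c))
            num = np.exp(a - mx)
            den = num + np.exp(b - mx) + np.exp(c - mx)
            S[i, j] = S[j, i] = (num / den).mean()
    np.fill_diagonal(S, 1.0)
    return RSM(S, list(ids) if ids is not None else None)


def rsm_correlation(A: RSM, B: RSM) -> float:
    """Pearson r between the strict upper triangles of two RSMs."""
    if A.m != B.m:
        raise ValueError("RSMs must cover the same objects")
    x, y = A.upper(), B.upper()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance RSM: correlation undefined")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class DimensionMatch:
    """Dimension pairing between two embeddings, sorted by descending r.

    ``pairs`` holds (source dim index, target dim index, Pearson r); with
    ``unique`` set, target dimensions are pairwise distinct (matching
    without replacement).
    """

    pairs: list[tuple[int, int, float]]
    unique: bool

    @property
    def source_dims(self) -> list[int]:
        return [p[0] for p in self.pairs]

    @property
    def target_dims(self) -> list[int]:
        return [p[1] for p in self.pairs]

    @property
    def correlations(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs,
                            columns=["source_dim", "target_dim", "r"])


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.sqrt((Ac ** 2).sum(axis=0))
    sb = np.sqrt((Bc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (Ac.T @ Bc) / np.outer(sa, sb)
    if (sa == 0).any() or (sb == 0).any():
        warnings.warn("constant dimension(s): correlations undefined, skipped")
    return C


def match_dimensions(A: PointEmbedding, B: PointEmbedding,
                     unique: bool = False) -> DimensionMatch:
    """Pair each dimension of A with its most correlated dimension of B.

    With replacement (``unique=False``) every A-dimension independently
    takes its max-|r| B-dimension; without replacement a greedy pass
    repeatedly claims the globally best remaining (A, B) pair, so each
    B-dimension is used at most once. Constant dimensions are skipped.
    """
    if A.object_ids != B.object_ids:
        raise ValueError("embeddings must cover the same objects in order")
    C = _corr_matrix(A.values, B.values)
    pairs: list[tuple[int, int, float]] = []
    if not unique:
        for a in range(A.k):
            row = C[a]
            if np.isnan(row).all():
                continue
            b = int(np.nanargmax(np.abs(row)))
            pairs.append((a, b, float(row[b])))
    else:
        Cw = np.abs(C.copy())
        Cw[np.isnan(Cw)] = -np.inf
        n_pairs = min(A.k, B.k)
        for _ in range(n_pairs):
            if not np.isfinite(Cw).any():
                break
            a, b = np.unravel_index(np.argmax(Cw), Cw.shape)
            pairs.append((int(a), int(b), float(C[a, b])))
            Cw[a, :] = -np.inf
            Cw[:, b] = -np.inf
    pairs.sort(key=lambda t: -abs(t[2]))
    return DimensionMatch(pairs, unique)


def cumulative_rsa(B: PointEmbedding, reference: RSM,
                   ranking: list[int],
                   context: str = "all", n_ctx: int = 1000,
                   seed: int = 0) -> np.ndarray:
    """Correlation with the reference RSM as ranked dimensions accumulate.

    For each prefix of ``ranking`` (starting at size 1) the RSM is rebuilt
    from that dimension subset alone and correlated with ``reference``;
    returns the r per prefix size.
    """
    if not ranking:
        raise ValueError("ranking must contain at least one dimension")
    rs = np.empty(len(ranking))
    for s in range(1, len(ranking) + 1):
        sub = B.subset(ranking[:s])
        rs[s - 1] = rsm_correlation(
            rsm_from_embedding(sub, context, n_ctx, seed), reference)
    return rs


def dims_needed(B: PointEmbedding, reference: RSM, ranking: list[int],
                variance_fraction: float = 0.95,
                mode: str = "relative",
                context: str = "all", n_ctx: int = 1000,
                seed: int = 0) -> int:
    """Smallest prefix of ``ranking`` reaching the target explained variance.

    In ``"relative"`` mode (default) the prefix r^2 must reach
    ``variance_fraction`` times the r^2 of the full embedding — the
    cumulative curve asymptotes to the full-embedding correlation, not to
    1. ``"absolute"`` compares r^2 to ``variance_fraction`` directly.
    """
    rs = cumulative_rsa(B, reference, ranking, context, n_ctx, seed)
    if mode == "relative":
        full_r = rsm_correlation(rsm_from_embedding(B, context, n_ctx, seed),
                                 reference)
        target = variance_fraction * full_r ** 2
    elif mode == "absolute":
        target = variance_fraction
    else:
        raise ValueError("mode must be 'relative' or 'absolute'")
    hits = np.nonzero(rs ** 2 >= target)[0]
    if len(hits) == 0:
        raise ValueError("no prefix reaches the requested variance fraction")
    return int(hits[0]) + 1


def explainable_variance(r: float, noise_ceiling_r2: float) -> float:
    """Fraction of explainable variance: r^2 normalized by the noise ceiling.

    The noise ceiling (maximal r^2 achievable given behavioural
    consistency) is supplied by the user. Values above 1 are possible for
    noisy ceilings and are flagged with a warning.
    """
    if not 0.0 < noise_ceiling_r2 <= 1.0:
        raise ValueError("noise ceiling must lie in (0, 1]")
    frac = r ** 2 / noise_ceiling_r2
    if frac > 1.0:
        warnings.warn("explained variance exceeds the noise ceiling")
    return float(frac)
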