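"""Triplet odd-one-out trials: containers, sampling and simulated choices.

In the odd-one-out task three objects are shown and the least similar one
is selected, implicitly marking the remaining pair as the most similar.
A simulated observer (a feature matrix standing in for a participant)
chooses the pair with the largest dot-product similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .features import FeatureMatrix, pair_similarity

__all__ = [
    "Triplet", "ChoiceRecord", "TripletDataset",
    "odd_one_out", "sample_triplets", "simulate_choices",
]

logger = logging.getLogger(__name__)

# The three candidate pairs of a sorted triplet (i, j, k), in canonical
# order; class c is the position of the chosen pair in this list, so the
# odd one out is the element not in PAIR_SLOTS[c].
PAIR_SLOTS = ((0, 1), (0, 2), (1, 2))
ODD_SLOT = (2, 1, 0)  # odd-one-out slot for each pair slot


class Triplet(NamedTuple):
    """Three distinct object indices in canonical ascending order."""

    i: int
    j: int
    k: int

    @classmethod
    def of(cls, a: int, b: int, c: int) -> "Triplet":
        if len({a, b, c}) != 3:
            raise ValueError(f"triplet indices must be distinct: {(a, b, c)}")
        i, j, k = sorted((a, b, c))
        return cls(i, j, k)


class ChoiceRecord(NamedTuple):
    """One resolved trial: the triplet, the most-similar pair, the odd one out."""

    triplet: Triplet
    pair: tuple[int, int]
    odd_one_out: int


@dataclass
class TripletDataset:
    """A set of resolved odd-one-out trials over ``m`` objects.

    Stored columnar for speed: ``triplets`` is an (n, 3) int array with
    rows sorted ascending, ``odd`` the chosen odd-one-out index per row.
    """

    triplets: np.ndarray
    odd: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.triplets = np.asarray(self.triplets, dtype=np.int64).reshape(-1, 3)
        self.odd = np.asarray(self.odd, dtype=np.int64).reshape(-1)
        if self.triplets.shape[0] != self.odd.shape[0]:
            raise ValueError("triplets and odd counts differ")
        if self.n and (self.triplets.min() < 0 or self.triplets.max() >= self.m):
            raise ValueError("object index out of range")
        if self.n and not (np.diff(self.triplets, axis=1) > 0).all():
            raise ValueError("triplet rows must be strictly ascending")
        if self.n and not (self.odd[:, None] == self.triplets).any(axis=1).all():
            raise ValueError("odd-one-out must be a member of its triplet")

    @property
    def n(self) -> int:
        return self.triplets.shape[0]

    def __len__(self) -> int:
        return self.n

    @property
    def choice_class(self) -> np.ndarray:
        """Index (0, 1, 2) of the chosen pair among ``PAIR_SLOTS`` per trial."""
        odd_slot = (self.triplets == self.odd[:, None]).argmax(axis=1)
        return np.asarray(ODD_SLOT)[odd_slot]

    @property
    def records(self) -> list[ChoiceRecord]:
        return list(self.iter_records())

    def iter_records(self) -> Iterator[ChoiceRecord]:
        for (i, j, k), o in zip(self.triplets, self.odd):
            t = Triplet(int(i), int(j), int(k))
            pair = tuple(x for x in t if x != o)
            yield ChoiceRecord(t, (pair[0], pair[1]), int(o))

    @classmethod
    def from_records(cls, records: Sequence[ChoiceRecord], m: int) -> "TripletDataset":
        trips = np.array([r.triplet for r in records], dtype=np.int64).reshape(-1, 3)
        odd = np.array([r.odd_one_out for r in records], dtype=np.int64)
        return cls(trips, odd, m)

    # ------------------------------------------------------------------ io
    def save(self, path: str | Path) -> None:
        """Tab-separated ``i j k odd``, 0-based, one trial per line."""
        arr = np.column_stack([self.triplets, self.odd])
        np.savetxt(path, arr, delimiter="\t", fmt="%d",
                   header="i\tj\tk\todd", comments="")

    @classmethod
    def load(cls, path: str | Path, m: int | None = None) -> "TripletDataset":
        arr = np.loadtxt(path, delimiter="\t", dtype=np.int64,
                         skiprows=_header_rows(path), ndmin=2)
        if arr.shape[1] != 4:
            raise ValueError("triplet file must have 4 columns: i j k odd")
        if m is None:
            m = int(arr[:, :3].max()) + 1
        return cls(arr[:, :3], arr[:, 3], m)


def _header_rows(path: str | Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.strip().startswith("i") else 0


def odd_one_out(features: FeatureMatrix, t: Triplet) -> ChoiceRecord:
    """Resolve a trial: the pair with the largest dot product is most similar.

    Ties are broken toward the lexicographically smallest sorted index
    pair, making the choice deterministic and permutation-stable.
    """
    t = Triplet.of(*t)
    sims = [pair_similarity(features, t[a], t[b]) for a, b in PAIR_SLOTS]
    best = int(np.argmax(sims))  # argmax takes the first maximum: lexicographic
    pair = (t[PAIR_SLOTS[best][0]], t[PAIR_SLOTS[best][1]])
    return ChoiceRecord(t, pair, t[ODD_SLOT[best]])


def sample_triplets(m: int, n: int, seed: int,
                    deduplicate: bool = False) -> np.ndarray:
    """Draw ``n`` uniform random triplets of distinct objects, canonical order.

    Trials are sampled independently, so the same triplet may recur across
    trials (never within one); ``deduplicate`` drops dataset-level repeats,
    which can return fewer than ``n`` rows.
    """
    if m < 3:
        raise ValueError("need at least 3 objects to form a triplet")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 3), dtype=np.int64)
    filled = 0
    while filled < n:
        chunk = rng.integers(0, m, size=(2 * (n - filled) + 16, 3))
        ok = chunk[(chunk[:, 0] != chunk[:, 1]) & (chunk[:, 0] != chunk[:, 2])
                   & (chunk[:, 1] != chunk[:, 2])]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    out.sort(axis=1)
    if deduplicate:
        _, idx = np.unique(out, axis=0, return_index=True)
        out = out[np.sort(idx)]
    return out


def simulate_choices(features: FeatureMatrix,
                     triplets: np.ndarray | Sequence[Triplet]) -> TripletDataset:
    """Apply the dot-product argmax rule to every triplet, preserving order.

    Ties in the three pair similarities are logged (count) and resolved by
    the lexicographic rule of :func:`odd_one_out`.
    """
    trips = np.asarray(triplets, dtype=np.int64).reshape(-1, 3)
    trips = np.sort(trips, axis=1)
    if trips.size and not (np.diff(trips, axis=1) > 0).all():
        raise ValueError("triplets must contain distinct indices")
    X = features.values
    if trips.size and (trips.min() < 0 or trips.max() >= features.m):
        raise IndexError("triplet index out of range for feature matrix")
    if trips.size == 0:
        return TripletDataset(trips.reshape(0, 3), np.empty(0, dtype=np.int64),
                              features.m)
    xi, xj, xk = (X[trips[:, 0]], X[trips[:, 1]], X[trips[:, 2]])
    sims = np.stack([(xi * xj).sum(1), (xi * xk).sum(1), (xj * xk).sum(1)],
                    axis=1)
    best = sims.argmax(axis=1)  # first maximum = lexicographic tie-break
    n_tied = int((np.isclose(sims, sims.max(axis=1, keepdims=True))
                  .sum(axis=1) > 1).sum())
    if n_tied:
        logger.info("simulate_choices: %d of %d trials had tied similarities "
                    "(resolved lexicographically)", n_tied, len(trips))
    odd = trips[np.arange(len(trips)), np.asarray(ODD_SLOT)[best]]
    return TripletDataset(trips, odd, features.m)
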