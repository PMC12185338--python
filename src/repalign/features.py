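"""Object feature matrices and the dot-product similarity they induce.

A :class:`FeatureMatrix` holds one row of numeric features per object
(e.g. penultimate-layer activations of a vision network, or a planted
synthetic embedding). Choice simulation treats similarity between two
objects as the raw inner product of their rectified feature rows — no
cosine normalisation or centering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FeatureMatrix", "rectify", "pair_similarity"]


def _default_ids(m: int) -> list[str]:
    return [f"obj_{i}" for i in range(m)]


@dataclass
class FeatureMatrix:
    """m x d matrix of object features with string object identifiers.

    Parameters
    ----------
    values : ndarray of shape (m, d)
        One feature row per object. Any real values; rectify before
        using dot-product similarity.
    object_ids : list of str, optional
        Unique identifiers, one per row. Defaults to ``obj_0 ... obj_{m-1}``.
    """

    values: np.ndarray
    object_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D array")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.object_ids is None:
            self.object_ids = _default_ids(self.m)
        if len(self.object_ids) != self.m:
            raise ValueError("object_ids length does not match row count")
        if len(set(self.object_ids)) != self.m:
            raise ValueError("object_ids must be unique")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def is_nonnegative(self) -> bool:
        return bool((self.values >= 0).all())

    # ------------------------------------------------------------------ io
    def save(self, path: str | Path) -> None:
        """Write features; ``.npz`` binary container or headerless TSV.

        A companion ``<stem>.ids.txt`` file with one object id per line is
        written next to TSV output.
        """
        path = Path(path)
        if path.suffix == ".npz":
            np.savez(path, features=self.values,
                     object_ids=np.asarray(self.object_ids))
        else:
            np.savetxt(path, self.values, delimiter="\t", fmt="%.10g")
            ids_path = path.with_suffix(path.suffix + ".ids.txt") \
                if path.suffix != ".tsv" else path.with_suffix(".ids.txt")
            ids_path.write_text("\n".join(self.object_ids) + "\n")

    @classmethod
    def load(cls, path: str | Path,
             object_ids: list[str] | None = None) -> "FeatureMatrix":
        path = Path(path)
        if path.suffix == ".npz":
            with np.load(path, allow_pickle=False) as data:
                values = data["features"]
                if object_ids is None and "object_ids" in data:
                    object_ids = [str(x) for x in data["object_ids"]]
        else:
            values = np.loadtxt(path, delimiter="\t", ndmin=2)
            ids_path = path.with_suffix(".ids.txt")
            if object_ids is None and ids_path.exists():
                object_ids = ids_path.read_text().split()
        return cls(values, object_ids)


def rectify(features: FeatureMatrix) -> FeatureMatrix:
    """Elementwise ``max(x, 0)``; returns a new matrix, shape preserved."""
    return FeatureMatrix(np.maximum(features.values, 0.0),
                         list(features.object_ids))


def pair_similarity(features: FeatureMatrix, a: int, b: int) -> float:
    """Inner product of feature rows ``a`` and ``b`` (symmetric in a, b)."""
    m = features.m
    if not (0 <= a < m and 0 <= b < m):
        raise IndexError(f"object index out of range for m={m}")
    return float(features.values[a] @ features.values[b])
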