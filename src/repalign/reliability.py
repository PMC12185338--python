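"""Split-half reliability of embedding runs and best-run selection.

Embeddings learned from the same triplet data under different seeds are
identified only up to column permutation and noise, so reproducibility is
assessed dimension-wise: for every dimension of a run, find the best
correlated dimension among all other runs using the odd-indexed objects,
then correlate that matched pair on the even-indexed objects. The
even-half correlations are Fisher z-transformed, averaged per run and
transformed back to an average Pearson r per run; the run with the
highest average is selected for downstream analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import PointEmbedding

__all__ = ["RunCollection", "split_half_reliability", "fisher_z",
           "inverse_fisher_z", "select_best_run"]

_R_CLIP = 1.0 - 1e-7


@dataclass
class RunCollection:
    """Point embeddings of several seeds over the same objects, same order."""

    runs: list[PointEmbedding]
    seeds: list[int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("need at least two runs")
        ids0 = self.runs[0].object_ids
        for r in self.runs[1:]:
            if r.object_ids != ids0:
                raise ValueError("runs must share object ids and order")
        if self.seeds is None:
            self.seeds = list(range(len(self.runs)))

    def __len__(self) -> int:
        return len(self.runs)


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z = atanh(r); |r| >= 1 is clipped just inside (-1, 1)."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        warnings.warn("|r| >= 1 clipped before Fisher z transform")
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z: float | np.ndarray) -> float | np.ndarray:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def _safe_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlations; constant columns give nan."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = np.sqrt((A ** 2).sum(axis=0))
    sb = np.sqrt((B ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (A.T @ B) / np.outer(sa, sb)
    C[:, sb == 0] = np.nan
    C[sa == 0, :] = np.nan
    return C


def split_half_reliability(runs: RunCollection,
                           masks: tuple[np.ndarray, np.ndarray] | None = None
                           ) -> np.ndarray:
    """Per-run mean split-half reliability r across all dimensions.

    ``masks`` optionally overrides the default object-position parity split
    (odd positions for matching, even positions for scoring), e.g. for a
    randomized-halves robustness check.
    """
    m = runs.runs[0].m
    if masks is None:
        odd = np.arange(m) % 2 == 1
        even = ~odd
    else:
        odd, even = masks
    out = np.empty(len(runs))
    for a, run in enumerate(runs.runs):
        others = np.column_stack([r.values for b, r in enumerate(runs.runs)
                                  if b != a])
        C_odd = _safe_corr_matrix(run.values[odd], others[odd])
        zs = []
        for d in range(run.k):
            row = C_odd[d]
            if np.isnan(row).all():
                warnings.warn(f"run {a} dim {d}: no defined odd-mask "
                              "correlation; excluded from the mean")
                continue
            best = int(np.nanargmax(np.abs(row)))
            r_even = _safe_corr_matrix(run.values[even][:, [d]],
                                       others[even][:, [best]])[0, 0]
            if np.isnan(r_even):
                warnings.warn(f"run {a} dim {d}: zero variance on even mask; "
                              "excluded from the mean")
                continue
            zs.append(fisher_z(r_even))
        out[a] = inverse_fisher_z(float(np.mean(zs))) if zs else np.nan
    return out


def select_best_run(runs: RunCollection,
                    reliabilities: np.ndarray | None = None) -> int:
    """Index of the run with maximal mean reliability; ties take the lowest."""
    if reliabilities is None:
        reliabilities = split_half_reliability(runs)
    return int(np.nanargmax(reliabilities))
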