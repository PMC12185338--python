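"""Sparse non-negative variational embeddings from odd-one-out choices.

The model learns, for ``m`` objects, a ``p``-dimensional embedding whose
rectified rows predict triplet odd-one-out behaviour: the probability that
a pair is judged most similar is the softmax of the three pairwise dot
products. Inference is mean-field variational — each weight w_ij gets an
independent Gaussian posterior q(w_ij) = N(mu_ij, sigma_ij^2) — under a
sparsity-inducing spike-and-slab Gaussian-mixture prior. Non-negativity is
enforced by rectifying sampled weights both during optimization and at
inference time. Dimensions whose posterior supports too few objects are
pruned at a fixed cadence; training stops once the dimensionality has been
stable for ``stability_epochs`` epochs or at ``max_epochs``.

The public surface is statsmodels-style: construct :class:`VICE` from a
:class:`~repalign.triplets.TripletDataset`, call :meth:`VICE.fit`, and work
with the returned :class:`VICEResults`. The module-level functions
(:func:`elbo_loss`, :func:`prune_dimensions`, ...) expose the individual
steps for testing and reuse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .features import FeatureMatrix
from .triplets import PAIR_SLOTS, Triplet, TripletDataset

__all__ = [
    "PriorSpec", "TrainConfig", "VariationalEmbedding", "PointEmbedding",
    "VICE", "VICEResults", "triplet_choice_probs", "sample_weights",
    "elbo_loss", "complexity_term", "posterior_prob_positive",
    "prune_dimensions", "point_estimate", "train",
]

_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = math.log(1e-4), math.log(10.0)


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class PriorSpec:
    """Spike-and-slab Gaussian mixture prior on embedding weights.

    ``pi`` is the spike mixture weight; the spike is a narrow zero-mean
    Gaussian (sd ``sigma_spike``) approximating a point mass at zero, the
    slab a wide zero-mean Gaussian (sd ``sigma_slab``). Setting
    ``sigma_spike == sigma_slab`` degenerates to a single Gaussian, which
    has a closed-form KL against the mean-field posterior and serves as a
    validation oracle.
    """

    pi: float = 0.5
    sigma_spike: float = 0.25
    sigma_slab: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie in (0, 1)")
        if self.sigma_spike <= 0 or self.sigma_slab <= 0:
            raise ValueError("prior standard deviations must be positive")
        if self.sigma_spike > self.sigma_slab:
            raise ValueError("sigma_spike must not exceed sigma_slab")

    @property
    def is_single_gaussian(self) -> bool:
        return self.sigma_spike == self.sigma_slab

    def log_pdf(self, w: np.ndarray) -> np.ndarray:
        comps = np.stack([
            math.log(self.pi) - 0.5 * (w / self.sigma_spike) ** 2
            - math.log(self.sigma_spike) - 0.5 * math.log(2 * math.pi),
            math.log(1.0 - self.pi) - 0.5 * (w / self.sigma_slab) ** 2
            - math.log(self.sigma_slab) - 0.5 * math.log(2 * math.pi),
        ])
        mx = comps.max(axis=0)
        return mx + np.log(np.exp(comps - mx).sum(axis=0))

    def neg_log_pdf_grad(self, w: np.ndarray) -> np.ndarray:
        """d(-log p(w))/dw for the mixture, computed responsibility-weighted."""
        la = math.log(self.pi) - 0.5 * (w / self.sigma_spike) ** 2 \
            - math.log(self.sigma_spike)
        lb = math.log(1.0 - self.pi) - 0.5 * (w / self.sigma_slab) ** 2 \
            - math.log(self.sigma_slab)
        mx = np.maximum(la, lb)
        ra = np.exp(la - mx)
        rb = np.exp(lb - mx)
        z = ra + rb
        return (ra * w / self.sigma_spike ** 2
                + rb * w / self.sigma_slab ** 2) / z


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for the variational embedding.

    ``p_init`` is the initial (over-complete) dimensionality that pruning
    cuts down; ``prune_threshold``/``prune_min_objects`` parameterize the
    retention rule (a dimension survives iff at least ``prune_min_objects``
    objects have Pr(w > 0) >= 1 - prune_threshold); ``stability_epochs``
    is how long the dimensionality must stay unchanged before stopping.
    """

    p_init: int = 150
    learning_rate: float = 0.01
    optimizer: str = "sgd"
    momentum: float = 0.9
    batch_size: int = 256
    max_epochs: int = 1000
    stability_epochs: int = 500
    prune_threshold: float = 0.05
    prune_min_objects: int = 5
    prune_interval: int = 50
    mc_samples: int = 1
    val_fraction: float = 0.1
    mu_init_scale: float = 0.1
    sigma_init: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_init < 1:
            raise ValueError("p_init must be >= 1")
        if not 0.0 < self.prune_threshold < 1.0:
            raise ValueError("prune_threshold must lie in (0, 1)")
        if self.prune_min_objects < 1:
            raise ValueError("prune_min_objects must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")


# ---------------------------------------------------------------------------
# embeddings


@dataclass
class VariationalEmbedding:
    """Mean-field posterior state: per-weight means and standard deviations.

    ``mu`` and ``sigma`` keep the full initialized shape (m, p);
    ``active_dims`` lists the retained column indices, in order. Pruning
    only shrinks ``active_dims``, so the rule is idempotent and the pruned
    columns remain inspectable.
    """

    mu: np.ndarray
    sigma: np.ndarray
    active_dims: list[int] = field(default=None)  # type: ignore[assignment]
    object_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 2:
            raise ValueError("mu and sigma must be 2-D arrays of equal shape")
        if not (self.sigma > 0).all():
            raise ValueError("sigma must be strictly positive")
        if self.active_dims is None:
            self.active_dims = list(range(self.mu.shape[1]))
        if self.object_ids is None:
            self.object_ids = [f"obj_{i}" for i in range(self.mu.shape[0])]

    @property
    def m(self) -> int:
        return self.mu.shape[0]

    @property
    def p(self) -> int:
        return self.mu.shape[1]

    @property
    def k(self) -> int:
        return len(self.active_dims)

    def save(self, path: str | Path) -> None:
        np.savez(path, mu=self.mu, sigma=self.sigma,
                 active_dims=np.asarray(self.active_dims, dtype=np.int64),
                 object_ids=np.asarray(self.object_ids))

    @classmethod
    def load(cls, path: str | Path) -> "VariationalEmbedding":
        with np.load(path, allow_pickle=False) as data:
            return cls(data["mu"], data["sigma"],
                       [int(x) for x in data["active_dims"]],
                       [str(x) for x in data["object_ids"]])


@dataclass
class PointEmbedding:
    """Rectified posterior-mean embedding: m objects x k retained dimensions."""

    values: np.ndarray
    object_ids: list[str] = field(default=None)  # type: ignore[assignment]
    dim_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("embedding values must be 2-D")
        if (self.values < 0).any():
            raise ValueError("point embedding must be non-negative")
        if self.object_ids is None:
            self.object_ids = [f"obj_{i}" for i in range(self.m)]
        if self.dim_ids is None:
            self.dim_ids = [f"dim_{j}" for j in range(self.k)]
        if len(self.dim_ids) != self.k or len(self.object_ids) != self.m:
            raise ValueError("id lengths inconsistent with value shape")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def subset(self, dims: list[int]) -> "PointEmbedding":
        return PointEmbedding(self.values[:, dims], list(self.object_ids),
                              [self.dim_ids[j] for j in dims])

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.object_ids,
                          columns=self.dim_ids)
        df.to_csv(path, sep="\t", index_label="object_id")

    @classmethod
    def load(cls, path: str | Path) -> "PointEmbedding":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(i) for i in df.index],
                   [str(c) for c in df.columns])


# ---------------------------------------------------------------------------
# elementary operations


def _rows(Y: PointEmbedding | np.ndarray, t: Triplet) -> np.ndarray:
    vals = Y.values if isinstance(Y, PointEmbedding) else np.asarray(Y, float)
    return vals[list(t)]


def triplet_choice_probs(Y: PointEmbedding | np.ndarray,
                         t: Triplet | tuple[int, int, int]) -> np.ndarray:
    """Softmax choice probabilities over the pairs ((i,j), (i,k), (j,k)).

    Rows are taken in the order given by ``t``; permuting the triplet
    permutes the probabilities accordingly. Overflow-safe.
    """
    r = _rows(Y, t)
    logits = np.array([r[0] @ r[1], r[0] @ r[2], r[1] @ r[2]])
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def sample_weights(emb: VariationalEmbedding, seed: int) -> np.ndarray:
    """One rectified reparameterized posterior draw relu(mu + sigma * eps)."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(emb.mu.shape)
    return np.maximum(emb.mu + emb.sigma * eps, 0.0)


def posterior_prob_positive(emb: VariationalEmbedding) -> np.ndarray:
    """Entrywise Pr(w_ij > 0) = 1 - Phi(-mu/sigma) under the posterior."""
    return ndtr(emb.mu / emb.sigma)


def prune_dimensions(emb: VariationalEmbedding,
                     threshold: float = 0.05,
                     min_objects: int = 5) -> VariationalEmbedding:
    """Drop dimensions supported by too few objects.

    A dimension is retained iff at least ``min_objects`` objects have
    Pr(w_ij > 0) >= 1 - threshold. Surviving dimensions keep their order;
    the rule is idempotent. Raises if nothing would survive.
    """
    prob = posterior_prob_positive(emb)
    support = (prob >= 1.0 - threshold).sum(axis=0)
    keep = [j for j in emb.active_dims if support[j] >= min_objects]
    if not keep:
        raise ValueError("pruning would remove every dimension")
    return replace(emb, active_dims=keep)


def point_estimate(emb: VariationalEmbedding) -> PointEmbedding:
    """Rectified posterior means on active dimensions, ordered by column sum.

    Columns are reported in descending order of total weight, the
    conventional ordering for sparse positive similarity embeddings
    (the first dimension carries the most mass).
    """
    vals = np.maximum(emb.mu[:, emb.active_dims], 0.0)
    order = np.argsort(-vals.sum(axis=0), kind="stable")
    dims = [emb.active_dims[j] for j in order]
    return PointEmbedding(vals[:, order], list(emb.object_ids),
                          [f"dim_{j}" for j in dims])


# ---------------------------------------------------------------------------
# objective


def complexity_term(emb: VariationalEmbedding, prior: PriorSpec,
                    rng: np.random.Generator | None = None,
                    n_samples: int = 1,
                    method: str = "hybrid") -> float:
    """E_q[log q(W) - log p(W)] summed over active weights.

    ``method`` selects the estimator:

    - ``"exact"``: closed-form Gaussian KL; valid only for the degenerate
      single-Gaussian prior (sigma_spike == sigma_slab).
    - ``"hybrid"`` (default): analytic entropy plus Monte-Carlo estimate of
      E_q[-log p(W)] with ``n_samples`` reparameterized draws.
    - ``"mc"``: both terms at sampled W. Under reparameterization the log-q
      part differs from the analytic entropy only by the constant
      (eps^2 - 1)/2 per weight, so the two estimators share one gradient.
    """
    mu = emb.mu[:, emb.active_dims]
    sigma = emb.sigma[:, emb.active_dims]
    if method == "exact":
        if not prior.is_single_gaussian:
            raise ValueError("exact complexity requires a single-Gaussian "
                             "prior (sigma_spike == sigma_slab)")
        s = prior.sigma_slab
        kl = (np.log(s / sigma) + (sigma ** 2 + mu ** 2) / (2 * s ** 2) - 0.5)
        return float(kl.sum())
    if rng is None:
        rng = np.random.default_rng(0)
    neg_entropy = -(0.5 * np.log(2 * math.pi * math.e * sigma ** 2)).sum()
    cross = 0.0
    logq_quad = 0.0
    for _ in range(n_samples):
        eps = rng.standard_normal(mu.shape)
        w = mu + sigma * eps
        cross += -prior.log_pdf(w).sum() / n_samples
        logq_quad += (-0.5 * np.log(2 * math.pi * sigma ** 2)
                      - 0.5 * eps ** 2).sum() / n_samples
    if method == "hybrid":
        return float(neg_entropy + cross)
    if method == "mc":
        return float(logq_quad + cross)
    raise ValueError(f"unknown complexity method {method!r}")


def _batch_nll(W: np.ndarray, trips: np.ndarray, choice: np.ndarray,
               return_grad: bool = False):
    """Mean negative log-likelihood of observed pair choices under rows W.

    W is the rectified (and dimension-masked) weight matrix. ``choice``
    encodes which of the canonical pairs ((i,j), (i,k), (j,k)) was chosen.
    When ``return_grad`` is set, also returns the gradient with respect to
    the rectified rows, scattered back to an (m, p) array.
    """
    xi, xj, xk = W[trips[:, 0]], W[trips[:, 1]], W[trips[:, 2]]
    logits = np.stack([(xi * xj).sum(1), (xi * xk).sum(1), (xj * xk).sum(1)],
                      axis=1)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    b = len(trips)
    nll = -np.log(probs[np.arange(b), choice]).mean()
    if not return_grad:
        return nll
    g = probs.copy()
    g[np.arange(b), choice] -= 1.0
    g /= b
    gi = g[:, [0]] * xj + g[:, [1]] * xk
    gj = g[:, [0]] * xi + g[:, [2]] * xk
    gk = g[:, [1]] * xi + g[:, [2]] * xj
    gW = np.zeros_like(W)
    np.add.at(gW, trips[:, 0], gi)
    np.add.at(gW, trips[:, 1], gj)
    np.add.at(gW, trips[:, 2], gk)
    return nll, gW


def elbo_loss(emb: VariationalEmbedding, prior: PriorSpec,
              batch: TripletDataset, n_total: int,
              seed: int | None = None, n_samples: int = 1,
              complexity_method: str = "hybrid") -> float:
    """Stochastic variational objective for one batch.

    complexity / n_total  +  mean batch NLL at a reparameterized rectified
    sample. Raises on a non-finite value with a diagnostic message.
    """
    if batch.n == 0:
        raise ValueError("batch must be non-empty")
    rng = np.random.default_rng(seed)
    comp = complexity_term(emb, prior, rng, n_samples, complexity_method)
    nll = 0.0
    mask = np.zeros(emb.p)
    mask[emb.active_dims] = 1.0
    for _ in range(n_samples):
        eps = rng.standard_normal(emb.mu.shape)
        W = np.maximum(emb.mu + emb.sigma * eps, 0.0) * mask
        nll += _batch_nll(W, batch.triplets, batch.choice_class) / n_samples
    loss = comp / n_total + nll
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite variational loss (complexity={comp:.3g}, nll={nll:.3g}); "
            "check learning rate and sigma initialization")
    return float(loss)


# ---------------------------------------------------------------------------
# model / results


class VICE:
    """Variational interpretable concept embedding model for triplet choices.

    Parameters
    ----------
    data : TripletDataset
        Observed (or simulated) odd-one-out trials.
    config : TrainConfig, optional
        Optimization and pruning settings.
    prior : PriorSpec, optional
        Spike-and-slab prior hyperparameters.
    object_ids : list of str, optional
        Identifiers for the ``data.m`` objects.

    Examples
    --------
    >>> model = VICE(dataset, TrainConfig(p_init=20, seed=0))
    >>> res = model.fit()
    >>> emb = res.point_estimate()
    """

    def __init__(self, data: TripletDataset,
                 config: TrainConfig | None = None,
                 prior: PriorSpec | None = None,
                 object_ids: list[str] | None = None) -> None:
        if data.n < 1:
            raise ValueError("dataset must contain at least one trial")
        self.data = data
        self.config = config or TrainConfig()
        self.prior = prior or PriorSpec()
        self.object_ids = object_ids or [f"obj_{i}" for i in range(data.m)]

    # -------------------------------------------------------------- fitting
    def fit(self, seed: int | None = None) -> "VICEResults":
        """Run stochastic variational optimization with iterative pruning."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        m, p = self.data.m, cfg.p_init

        mu = np.abs(rng.normal(0.0, cfg.mu_init_scale, size=(m, p)))
        log_sigma = np.full((m, p), math.log(cfg.sigma_init))
        mask = np.ones(p)
        active = list(range(p))

        n_val = int(round(cfg.val_fraction * self.data.n))
        perm0 = rng.permutation(self.data.n)
        val_idx, train_idx = perm0[:n_val], perm0[n_val:]
        trips_all = self.data.triplets
        choice_all = self.data.choice_class
        trips, choice = trips_all[train_idx], choice_all[train_idx]
        n = len(trips)
        if n == 0:  # tiny datasets: train on everything, no held-out log
            trips, choice = trips_all, choice_all
            n, val_idx = len(trips), np.empty(0, dtype=int)

        # Adam state
        m1_mu = np.zeros_like(mu); m2_mu = np.zeros_like(mu)
        m1_ls = np.zeros_like(mu); m2_ls = np.zeros_like(mu)
        b1, b2, eps_adam = 0.9, 0.999, 1e-8
        t_step = 0

        history: list[dict] = []
        last_change_epoch = 0
        diverged = False
        epoch = 0
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                bt, bc = trips[idx], choice[idx]
                sigma = np.exp(log_sigma)
                eps = rng.standard_normal((m, p))
                W = np.maximum(mu + sigma * eps, 0.0) * mask
                nll, gW = _batch_nll(W, bt, bc, return_grad=True)
                act = (mu + sigma * eps) > 0
                gW = gW * act * mask
                g_mu = gW.copy()
                g_ls = gW * sigma * eps
                # complexity gradient at the same sample, weight 1/n
                g_prior = self.prior.neg_log_pdf_grad(mu + sigma * eps) * mask
                g_mu += g_prior / n
                g_ls += (g_prior * sigma * eps - mask) / n
                if not np.isfinite(nll) or not np.isfinite(g_mu).all():
                    diverged = True
                    break
                t_step += 1
                if cfg.optimizer == "adam":
                    for g, m1, m2, theta in ((g_mu, m1_mu, m2_mu, mu),
                                             (g_ls, m1_ls, m2_ls, log_sigma)):
                        m1 *= b1; m1 += (1 - b1) * g
                        m2 *= b2; m2 += (1 - b2) * g * g
                        mhat = m1 / (1 - b1 ** t_step)
                        vhat = m2 / (1 - b2 ** t_step)
                        theta -= cfg.learning_rate * mhat / (np.sqrt(vhat)
                                                             + eps_adam)
                elif cfg.optimizer == "sgd":
                    for g, m1, theta in ((g_mu, m1_mu, mu),
                                         (g_ls, m1_ls, log_sigma)):
                        m1 *= cfg.momentum; m1 += g
                        theta -= cfg.learning_rate * m1
                else:
                    raise ValueError("optimizer must be 'adam' or 'sgd'")
                np.clip(log_sigma, _LOG_SIGMA_MIN, _LOG_SIGMA_MAX, out=log_sigma)
                epoch_loss += nll
                n_batches += 1
            if diverged:
                break

            emb = VariationalEmbedding(mu, np.exp(log_sigma), active,
                                       self.object_ids)
            if cfg.prune_interval and epoch % cfg.prune_interval == 0:
                try:
                    pruned = prune_dimensions(emb, cfg.prune_threshold,
                                              cfg.prune_min_objects)
                except ValueError:
                    pruned = emb  # defer: no dimension has support yet
                if pruned.k != len(active):
                    active = pruned.active_dims
                    mask = np.zeros(p)
                    mask[active] = 1.0
                    last_change_epoch = epoch
            rec = {"epoch": epoch, "nll": epoch_loss / max(n_batches, 1),
                   "n_dims": len(active)}
            if len(val_idx) and (epoch % 10 == 0 or epoch == 1):
                emb_now = VariationalEmbedding(mu, np.exp(log_sigma), active,
                                               self.object_ids)
                rec["val_accuracy"] = _accuracy(point_estimate(emb_now),
                                                trips_all[val_idx],
                                                choice_all[val_idx])
            history.append(rec)
            if epoch - last_change_epoch >= cfg.stability_epochs:
                break

        emb = VariationalEmbedding(mu, np.exp(log_sigma), active,
                                   self.object_ids)
        if cfg.max_epochs > 0 and cfg.prune_interval > 0 and not diverged:
            try:
                emb = prune_dimensions(emb, cfg.prune_threshold,
                                       cfg.prune_min_objects)
            except ValueError:
                pass  # under-trained state: keep all dimensions

            # drop any retained dimension whose rectified mean column is empty
            nz = [j for j in emb.active_dims
                  if np.maximum(emb.mu[:, j], 0.0).any()]
            if nz:
                emb = replace(emb, active_dims=nz)
        return VICEResults(self, emb, pd.DataFrame(history), seed,
                           n_epochs=epoch, diverged=diverged)


def _accuracy(Y: PointEmbedding, trips: np.ndarray,
              choice: np.ndarray) -> float:
    W = Y.values
    xi, xj, xk = W[trips[:, 0]], W[trips[:, 1]], W[trips[:, 2]]
    logits = np.stack([(xi * xj).sum(1), (xi * xk).sum(1), (xj * xk).sum(1)],
                      axis=1)
    return float((logits.argmax(axis=1) == choice).mean())


class VICEResults:
    """Fit results: variational state, training history and diagnostics."""

    def __init__(self, model: VICE, embedding: VariationalEmbedding,
                 history: pd.DataFrame, seed: int, n_epochs: int,
                 diverged: bool) -> None:
        self.model = model
        self.embedding = embedding
        self.history = history
        self.seed = seed
        self.n_epochs = n_epochs
        self.diverged = diverged

    @property
    def n_dims(self) -> int:
        return self.embedding.k

    def point_estimate(self) -> PointEmbedding:
        return point_estimate(self.embedding)

    def predict_proba(self, triplets: np.ndarray) -> np.ndarray:
        """Choice probabilities (n, 3) over canonical pairs per triplet."""
        Y = self.point_estimate().values
        trips = np.asarray(triplets, dtype=np.int64).reshape(-1, 3)
        xi, xj, xk = Y[trips[:, 0]], Y[trips[:, 1]], Y[trips[:, 2]]
        logits = np.stack([(xi * xj).sum(1), (xi * xk).sum(1),
                           (xj * xk).sum(1)], axis=1)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def accuracy(self, data: TripletDataset) -> float:
        """Fraction of trials whose observed choice is the modal prediction."""
        return _accuracy(self.point_estimate(), data.triplets,
                         data.choice_class)

    def summary(self) -> str:
        Y = self.point_estimate()
        sums = Y.values.sum(axis=0)
        lines = [
            "Variational embedding fit",
            "=" * 60,
            f"objects:              {self.embedding.m}",
            f"trials:               {self.model.data.n}",
            f"initial dimensions:   {self.model.config.p_init}",
            f"retained dimensions:  {self.n_dims}",
            f"epochs run:           {self.n_epochs}",
            f"seed:                 {self.seed}",
            f"diverged:             {self.diverged}",
            f"train accuracy:       {self.accuracy(self.model.data):.4f}",
            "-" * 60,
            "dimension  total_weight  n_nonzero_objects",
        ]
        for name, s, col in zip(Y.dim_ids, sums, Y.values.T):
            lines.append(f"{name:<10} {s:>12.4f}  {int((col > 0).sum()):>17d}")
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Loss and dimensionality trajectories over epochs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["nll"],
                label="mean batch NLL")
        ax2 = ax.twinx()
        ax2.plot(self.history["epoch"], self.history["n_dims"], color="C1",
                 label="dimensions")
        ax.set_xlabel("epoch")
        ax.set_ylabel("NLL")
        ax2.set_ylabel("active dimensions")
        return ax


def train(data: TripletDataset, config: TrainConfig | None = None,
          prior: PriorSpec | None = None,
          object_ids: list[str] | None = None) -> VICEResults:
    """Functional entry point: fit a :class:`VICE` model and return results."""
    return VICE(data, config, prior, object_ids).fit()
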