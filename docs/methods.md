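# Methods

## Choice model and simulated observers

A trial presents three distinct objects {i, j, k}; the observer selects
the odd one out, equivalently the most-similar pair {a, b}. A simulated
observer is any feature matrix: its similarity for a pair is the raw dot
product of the two rectified feature rows (no cosine normalization, no
centering), and it deterministically chooses the pair with the largest
dot product. Ties are broken toward the lexicographically smallest sorted
index pair — deterministic and stable under permutation of the triplet —
and the simulator logs how many trials were tied rather than resolving
them silently. Triplets are sampled uniformly and independently, so the
same triplet may recur across trials (an optional flag deduplicates);
indices are 0-based everywhere, and stored triplets are canonically
sorted ascending.

## Variational embedding

The embedding W is an m x p matrix of non-negative object weights. The
likelihood of a choice is the softmax over the three pairwise dot
products of the (rectified) rows. The posterior over W is approximated
mean-field, q(w_ij) = N(mu_ij, sigma_ij^2), under an independent
spike-and-slab prior p(w) = pi N(0, sigma_spike^2) + (1-pi) N(0,
sigma_slab^2). The per-trial objective is complexity/n + NLL, with the
complexity term E_q[log q - log p]. Two estimators of the complexity
value are provided: `hybrid` (analytic Gaussian entropy plus Monte-Carlo
cross-entropy against the mixture prior; the default) and `mc` (both
terms at the sampled W). Under the reparameterization W = mu + sigma*eps
the sampled log q equals the analytic entropy up to the theta-independent
constant (eps^2 - 1)/2 per weight, so both estimators induce the same
gradient; the gradient path uses the analytic entropy. For the degenerate
single-Gaussian prior (sigma_spike = sigma_slab) the closed-form Gaussian
KL is available (`exact`) and serves as a validation oracle for the
Monte-Carlo estimators.

Gradients are derived analytically (softmax cross-entropy through the
pair dot products, masked by the rectification indicator, scattered back
to the object rows; mixture-prior score for the complexity part) and
implemented in NumPy. One reparameterized sample per step is used, the
standard choice for this family; the count is configurable.

### Optimizer

The default optimizer is plain SGD with momentum 0.9 and learning rate
0.01. This is a deliberate choice over adaptive methods: with
deterministic (argmax-simulated) choices the likelihood rewards sheer
logit scale, and an adaptive per-parameter step (Adam) grows *every*
column at the same rate regardless of gradient magnitude, recruiting
redundant correlated dimensions that the weak (1/n-scaled) prior can
never remove — in recovery experiments nearly all of p_init dimensions
survive. Gradient-proportional SGD steps instead give rich-get-richer
dynamics: dimensions that explain the data grow quickly, the rest stay
near initialization where their posterior support is low and the pruning
rule removes them. With SGD the planted dimensionality is recovered to
within a few dimensions across seeds. Adam remains available
(`TrainConfig(optimizer="adam")`) for stochastic, human-like data where
scale is bounded by the choice noise.

### Initialization, pruning, stopping

mu is initialized half-normal (|N(0, 0.1^2)|, non-negative to cooperate
with rectification), sigma constant at 0.5. Every `prune_interval` = 50
epochs a dimension is retained only if at least `prune_min_objects` = 5
objects give it Pr(w_ij > 0) = Phi(mu/sigma) >= 1 - `prune_threshold` =
0.95; pruned dimensions are frozen (excluded from the likelihood and from
updates) so the dimensionality trajectory is monotone and the stopping
rule — dimensionality unchanged for 500 epochs, or 1000 epochs total —
is well defined. The retention rule is stated in the "support counting"
direction deliberately: counting objects *below* a low threshold would
prune exactly the dense, well-supported dimensions, contradicting the
intent that weakly supported dimensions go. If at some cadence no
dimension yet meets the support criterion (very short or under-trained
runs), that pruning pass is deferred rather than emptying the embedding;
the standalone `prune_dimensions` still raises in that case. The final
embedding is the rectified posterior mean on retained dimensions, with
columns ordered by descending column sum so "the top dimension" is well
defined. A held-out fraction (default 10%) is used only to log accuracy,
never for stopping.

The pruning cadence interacts with problem scale: pruning too early (few
optimization steps per epoch at small n) can cut dimensions before they
have grown into their support. The shipped defaults (cadence 50, batch
256) are tuned for the package's reference study scale of ~50k trials on
~60 objects; smaller datasets may need a later first prune.

### Prior defaults

pi = 0.5, sigma_spike = 0.25, sigma_slab = 1.0 — a weakly informative
sparsity prior in the Bayesian-elastic-net spirit; all three are
configurable. At the 1/n weighting the prior's numerical influence per
step is small; sparsity in practice comes from the optimizer dynamics
plus the pruning rule, with the prior setting the direction of shrinkage.

## Reliability and run selection

Runs from different seeds are identified only up to column permutation,
sign-free scaling and noise. Split-half reliability: objects are split by
stored-order parity (odd positions for matching, even for scoring; a
custom mask pair can be supplied for randomized-halves checks). For each
dimension of each run, the best-|r| correlate on the odd half is found
among all dimensions of all other runs pooled (many-to-one matching is
allowed — the procedure imposes no uniqueness); the matched pair is then
correlated on the even half, Fisher z-transformed, averaged per run, and
transformed back. Correlations of exactly ±1 are clipped to 1 - 1e-7
before atanh, with a warning; zero-variance dimensions on a mask are
excluded from the mean, with a warning. The run with the highest average
r is selected (ties to the lowest index).

## Feature mapping

An l2-regularized linear regression links features to embedding
dimensions. The penalty is selected per embedding dimension by K-fold
(default 5) cross-validated R^2 over a logarithmic grid 1e-3..1e3, with
seeded shuffling; the reported R^2 per dimension is the held-out value at
the chosen penalty, and the final coefficients are refitted on all
objects. Predictions are rectified by default to preserve the
non-negative embedding invariant (raw affine values are available). The
activation-maximization objective is exposed as a pure function:
-alpha*y_j - beta*log p_j with softmax specificity p_j =
exp(y_j)/sum_l exp(y_l); the generative image-search loop that would
minimize it requires external pretrained generators and is out of scope.

## RSM construction and comparison

S_ij is the probability that (i, j) is judged most similar in a triplet
with context k, averaged over all contexts k not in {i, j} (exact
enumeration, O(m^3), overflow-safe via max-subtraction) or over a
uniform sample of contexts (default 1000 per pair) for large m. The
diagonal is set to 1 by convention. RSM correlation is Pearson on the
strict upper triangle of raw values (no rank transform; exposed as the
single place to change if a rank-based variant is wanted). Dimension
matching: with replacement, each source dimension independently takes
its max-|r| target; without replacement, greedy on the globally best
remaining pair — equivalent to lexicographically maximizing the sorted
|r| sequence, which is the natural reading of sequential best-match
without reuse (Hungarian assignment would optimize the sum instead, a
different criterion). Cumulative analysis rebuilds the RSM from growing
ranked prefixes; `dims_needed` is relative by default — the prefix r^2
must reach the requested fraction of the *full embedding's* r^2, since
the curve asymptotes to the full-embedding correlation, not to 1 — with
an absolute mode available. Explainable variance divides r^2 by a
user-supplied noise ceiling; estimating the ceiling from repeated trials
is out of scope.

## Jackknife relevance

For a triplet, the tracked probability is that of the pair the full
embedding predicts most similar. Each dimension is removed in turn and
the probability recomputed; delta_d = p_full - p_without_d. Rankings use
|delta| (a dimension can matter by raising or lowering the prediction)
while the signed value is reported. Divergence between two embeddings on
a triplet is 0 when they predict the same pair, otherwise the mean of
their two confidences — monotone in both and zero under agreement.

## Synthetic ground truth

The generator plants a sparse non-negative embedding (entries zero with
the configured probability, otherwise exponential with mean `scale`;
empty columns resampled), an optional feature matrix features =
embedding @ loading^T + noise (non-negative loading, rectified output)
whose dot-product geometry mirrors the embedding, and triplet datasets
resolved by argmax or by softmax sampling at a temperature (temperature 1
matches the model likelihood exactly; temperature -> 0 recovers argmax
almost surely for dense embeddings — sparse rows can produce exact
dot-product ties, which argmax resolves lexicographically but softmax
leaves uniform). Everything is bit-reproducible from seeds. What the
generator does *not* emulate: category structure and semantic
organization of real object sets, inter-individual variability, lapses
and response biases in human choices, and the heavy redundancy of real
network features. Passing recovery tests therefore shows the inference
machinery is correct and well calibrated at this scale, not that
real-data embeddings of any particular stimulus set are faithful.

## Reference study scale

The bundled study (tests and `scripts/acceptance.py`) uses 60 objects, a
planted 6-dimensional truth at 60% sparsity, 50k argmax trials, p_init =
20, up to 1000 epochs — a size at which the full protocol, three seeds
included, completes in minutes on one CPU while exercising every stage.
At this scale the model recovers the planted dimensions at median
matched r ≈ 0.92–0.98, dimensionality within ±3 of truth, RSM agreement
r ≈ 0.85–0.93, and held-out accuracy ≈ 0.9 against the deterministic
generator.

## Known limitations

- Deterministic argmax data makes the likelihood scale-hungry; the fitted
  logit scale is not interpretable as a choice temperature.
- Pruned dimensions cannot revive; an over-aggressive early prune at
  small data scales is irreversible (see cadence note above).
- The greedy no-reuse matcher is order-dependent by design; use the
  with-replacement matcher when reuse is meaningful.
- Exact RSM enumeration is O(m^3); beyond a few hundred objects use
  sampled contexts.
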