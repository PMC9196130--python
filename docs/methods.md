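# Methods

## Model

`danrlca` learns low-dimensional node representations for undirected,
unweighted graphs with optional nonnegative node attributes. Three sources of
signal are fused:

1. **Microscopic structure** — the adjacency matrix A.
2. **Attribute semantics** — pairwise cosine similarity of attribute vectors,
   motivated by homophily: nodes with similar attributes tend to relate.
3. **Community structure** — a hard partition of the nodes (label
   propagation, multilevel modularity optimization, or an external file),
   encoded as a one-hot indicator matrix C.

These are blended into a *reconstructed adjacency* R, which replaces A as the
description of each node's neighborhood:

* **AM variant** — community indicators are appended to the attributes,
  W = [X | C], and R = ηA + ψ·cos(W);
* **CSM variant** — each source keeps its own weight,
  R = ηA + ψ·cos(X) + φ·cos(C).

CSM is the default: it can rebalance attribute and community influence
independently, which matters when either source is sparse or noisy. The
mixing weights η, ψ, φ default to 1.0 and are conventionally tuned over the
benchmark grid {0.5, 1.0, 1.5, 2.0, 2.5}.

Two coupled branches share one encoder (a strictly decreasing tanh tower
ending at dimension d):

* **Neighborhood-enhancement autoencoder** (second-order proximity): rows of
  R are encoded to d dimensions and decoded through a mirrored tanh tower.
  The squared reconstruction error is weighted elementwise by
  B (b_ij = χ > 1 on the nonzero support of R, 1 elsewhere), so observed
  relations dominate the overwhelmingly sparse zeros. χ defaults to 10.
* **Community-aware skip-gram** (high-order proximity): random walks
  (second-order biased with return/in-out parameters p, q; uniform at the
  default p = q = 1) produce (center, context) pairs within a window b. The
  encoder output y_i of the center is scored against a free context matrix H
  (one d-vector per node), with the negative-sampling logistic loss: each
  observed pair is contrasted with |neg| noise nodes drawn i.i.d. with
  P(v) ∝ degree(v)^{3/4} through an alias table (O(1) per draw).

The joint objective is

    L = L_sg + α · L_ae + γ · L_reg,     L_reg = ½ Σ_k (‖W^(k)‖_F² + ‖Ŵ^(k)‖_F²),

with α = 1 (branch balance), γ = 1e-4 (weight decay on encoder/decoder
weights only; biases and H are not penalized).

## Optimization

Gradients of all three components are derived in closed form (backprop
through the tanh towers) and checked against central finite differences in
the test suite (max relative error < 1e-4 on a 6-node fixture). A single Adam
optimizer (lr 1e-3, β = 0.9/0.999) holds state for all parameters.

Each epoch shuffles the context pairs and the rows of R, then walks through
skip-gram pair batches (default 1024 pairs; centers are deduplicated within
a batch before encoding). `ae_passes` full autoencoder sweeps (row batches of
64, default 5 sweeps) are spread evenly among the skip-gram batches. Strict
one-for-one alternation was rejected because the pair stream outnumbers the
row batches by roughly the average context count per node (~50:1 at desk
scale), which would re-run the autoencoder ~50 epochs per skip-gram epoch and
dominate runtime without a quality benefit.

Numerical choices:

* Rows of R are scaled by their maximum absolute entry before training.
  The decoder's tanh output lies in (−1, 1) and cannot reach raw R values
  above 1; per-row max-normalization makes every row representable while
  preserving within-row structure.
* The nonzero test for B uses |r_ij| > 1e-12 (float arithmetic on ψ·cosine
  terms).
* Zero-vector cosine similarity is defined as 0, including self-similarity:
  an attribute-less node is similar to no one.
* Training stops early when the relative epoch-loss change stays below 1e-5
  for 5 consecutive epochs; otherwise it runs the fixed epoch budget
  (default 50). A non-finite loss aborts with a diagnostic.
* LPA ties between equally frequent neighbor labels are broken uniformly at
  random with the seeded generator; the sweep loop is asynchronous
  (in-place), capped at 100 sweeps.
* The multilevel detector logs modularity after every two-phase pass and
  asserts it never decreases; phase-2 contraction keeps integer edge weights
  as self-loops/multiplicities.

All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
two runs with the same seed are bit-for-bit identical.

## Evaluation protocols

* **Node classification**: sample 30% of the labeled nodes (resampling until
  every class is represented), fit a linear SVM (hinge loss, C = 1.0, fixed
  random state for determinism) on their embeddings, score Micro-F1 and
  Macro-F1 on the rest, and average over 10 repeats. The hinge loss is
  preferred over regularized logistic regression because on very small,
  imbalanced training splits the logistic intercept biases predictions
  toward the majority class even when classes are perfectly separable.
* **Link prediction**: remove ⌊frac·|E|⌋ edges (default 50%) visiting edges
  in seeded random order and skipping bridges, so the residual graph stays
  connected; an unreachable target is an error reporting the achieved count.
  Negatives are non-adjacent pairs of the original graph, sampled uniformly
  without replacement, one per removed edge (capped with a warning on
  degenerate near-complete graphs). Embeddings are trained on the residual
  graph; removed edges are ranked against negatives by cosine similarity and
  scored with the exact pairwise AUC (ties count ½). A zero embedding vector
  scores 0 and is logged.
* **NMI** (arithmetic-mean normalization) measures partition agreement; the
  degenerate case of two single-cluster partitions is defined as 1.

## Synthetic data

`attributed_sbm` draws a balanced planted-partition graph: within-block edge
probability p_in, between-block p_out, remainder nodes joining the last
block. Attribute columns are split evenly among blocks; a node activates its
own block's attributes with probability `attr_signal` and any other with
`attr_noise`. Defaults (n = 300, 3 blocks, p_in = 0.1, p_out = 0.005, f = 60,
signal 0.3, noise 0.02) give a sparse assortative graph (mean degree ≈ 11)
with weakly informative attributes — detectable but not trivial.

What the generator does *not* emulate: degree heterogeneity (no
degree-corrected blocks), overlapping or hierarchical communities, weighted
or TF-IDF attributes, and homophily that varies by node. Passing the
recovery experiments therefore shows the pipeline is correct and the model
can exploit planted structure; it does not certify performance on real
citation or connectome data.

## Recovery experiments (`danrlca.experiments`)

Problem sizes are chosen so a full experiment runs on one CPU in minutes:
the CSM variant with tower 300–128–32 (d = 32), 50 epochs, walk corpus of 5
walks × length 20 per node, window 5, 5 negatives, skip-gram batches of
2048. The package defaults stay at the literature-scale settings (d = 128,
10 walks × length 80, window 10, 10 negatives, 1000–500 towers).

* `block_recovery_nmi` — train on the full graph, k-means the embedding into
  the planted number of blocks, report NMI per seed and the median over 3
  seeds. At the default conditions the median is 1.0.
* `link_prediction_auc` — 50% connectivity-preserving holdout, train on the
  residual graph, exact cosine AUC. The community weight φ is tuned over
  {0.5, 1.0, 2.5} (a coarse cut of the benchmark grid), mirroring the
  per-task grid-search convention for the mixing weights.
* `untrained_auc` — the same split scored with randomly initialized
  embeddings; sits at chance (≈ 0.5).

A note on the AUC ceiling at these conditions: with p_in = 0.1 and half the
edges removed, a within-block pair has ≈ 0.25 expected common neighbors in
the residual graph, so pair-specific local evidence is almost absent
(common-neighbor AUC ≈ 0.54). The task is then essentially block
recognition, whose exact AUC — scoring a pair 1 iff same block — is 0.796 to
0.818 across seeds (0.801 at seed 0); ranking the raw rows of R does no
better. A trained 32-d embedding approaches this ceiling from below
(measured 0.787–0.797, vs ≈ 0.50 untrained). Larger AUC values on this task
would require denser graphs or a smaller removed fraction, not a better
optimizer.

## Known limitations

* The model is transductive: embeddings exist only for nodes seen at fit
  time (`transform` returns the fitted matrix).
* Dense R (n×n) bounds practical graph size to ~20k nodes in 8 GiB; the
  similarity construction is dense by definition.
* The community detectors are unweighted; externally computed assignments
  (e.g. flow-based methods) enter through `load_assignment`.
* Multi-label nodes are out of scope; labels are single-class.
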