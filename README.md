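# danrlca

Community-aware attributed network embedding: learn low-dimensional node
representations for undirected, unweighted graphs that preserve microscopic
structure, node-attribute semantics, and mesoscopic community structure at
once. The target users are network scientists working with citation graphs,
social networks, and connectomes who need embeddings for downstream node
classification and link prediction — including structure-only networks such
as neuron-level brain wiring graphs, where community structure carries much
of the signal.

## Model

Let G = (V, E, A, X) be a graph with n nodes, binary adjacency A and an
optional nonnegative attribute matrix X, and let C be the one-hot indicator
of a hard community partition (label propagation, multilevel modularity
optimization, or an externally supplied assignment). The graph is summarized
by a *reconstructed adjacency*

    AM:   R = η A + ψ cos(W),  W = [X | C]
    CSM:  R = η A + ψ cos(X) + φ cos(C)

where cos(·) is row-wise cosine similarity. Two branches share one tanh
encoder tower ending at dimension d:

* an **autoencoder** reconstructs each row R_i through a mirrored decoder,
  with squared error weighted by b_ij = χ > 1 on the nonzero support of R
  (second-order proximity);
* a **skip-gram with negative sampling** scores random-walk
  (center, context) pairs, using the encoder output y_i as the center
  representation and a free context matrix H′, against noise nodes drawn
  with P(v) ∝ d_v^{3/4} (high-order proximity).

The joint objective

    L = L_sg + α L_ae + γ L_reg,   L_reg = ½ Σ_k (‖W^(k)‖_F² + ‖Ŵ^(k)‖_F²)

is minimized by alternating mini-batches of both branches under one Adam
optimizer; the embedding is the encoder output Y ∈ R^{n×d}. Gradients are
closed-form and finite-difference checked. See `docs/methods.md` for
defaults, numerical conventions, and the evaluation protocols.

## Worked example

```python
import numpy as np
from sklearn.cluster import KMeans

from danrlca import (DANRLCA, SBMSpec, attributed_sbm, nmi,
                     link_prediction_split, auc_ranking)

# a 120-node planted-partition graph with block-correlated attributes
spec = SBMSpec(n=120, num_blocks=3, p_in=0.2, p_out=0.01, f=30,
               attr_signal=0.4, attr_noise=0.03, seed=7)
graph, truth = attributed_sbm(spec)
print(f"graph: {graph.n} nodes, {graph.num_edges} edges, "
      f"{graph.X.shape[1]} attributes")

model = DANRLCA(variant="csm", dim=16, hidden_layers=(64,), epochs=30,
                walks_per_node=5, walk_length=15, window=5,
                num_negatives=5, seed=0)
model.fit(graph)                      # detects communities, builds R, trains
print(f"detected {model.community_.l} communities; "
      f"final loss {model.loss_history_[-1]:.1f}")

labels = KMeans(3, n_init=10, random_state=0).fit_predict(model.embedding_)
print(f"block-recovery NMI: {nmi(labels, truth.membership):.3f}")

split = link_prediction_split(graph, frac=0.5, seed=0)   # stays connected
lp_model = DANRLCA(variant="csm", dim=16, hidden_layers=(64,), epochs=30,
                   walks_per_node=5, walk_length=15, window=5,
                   num_negatives=5, seed=0).fit(split.train_graph)
print(f"link-prediction AUC: {auc_ranking(lp_model.embedding_, split):.3f}")
```

Output:

```
graph: 120 nodes, 495 edges, 30 attributes
detected 3 communities; final loss 178081.1
block-recovery NMI: 0.964
link-prediction AUC: 0.785
```

The multilevel detector finds the three planted blocks; clustering the
16-dimensional embedding recovers them almost perfectly (NMI 0.964, where 1
means identical partitions). After hiding half the edges, cosine ranking of
the embeddings separates held-out edges from non-edges far above the 0.5
chance level — on this sparse generator most of the attainable signal is
block membership, so values near 0.8 are close to the task's ceiling (see
`docs/methods.md`).

The same pipeline is available from the shell:

```sh
danrl-ca simulate --n 120 --blocks 3 --p-in 0.2 --p-out 0.01 --f 30 \
    --seed 7 --out-prefix /tmp/sbm
danrl-ca communities --edges /tmp/sbm.edges --method multilevel --seed 0
danrl-ca embed --edges /tmp/sbm.edges --attributes /tmp/sbm.attrs \
    --variant csm --dim 16 --epochs 30 --seed 0 --out /tmp/sbm.emb
danrl-ca evaluate nc --embedding /tmp/sbm.emb --edges /tmp/sbm.edges \
    --labels /tmp/sbm.labels
```

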