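"""Task protocols: repeated-split node classification and
connectivity-preserving link prediction, plus NMI for partition recovery.

Link prediction removes a fraction of edges while keeping the training graph
connected, learns embeddings on the residual graph, and ranks removed edges
against an equal number of sampled non-edges by cosine similarity (exact
pairwise AUC). Node classification fits a regularized linear classifier on a
random 30% of the labeled nodes, evaluates Micro/Macro-F1 on the rest, and
averages over repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.svm import LinearSVC
from sklearn.metrics import f1_score, normalized_mutual_info_score

from .graph_io import AttributedGraph, Embedding

logger = logging.getLogger(__name__)

__all__ = [
    "LinkSplit",
    "link_prediction_split",
    "auc_ranking",
    "node_classification_eval",
    "nmi",
]


@dataclass
class LinkSplit:
    """A connectivity-preserving edge holdout.

    ``train_graph`` stays connected; ``pos_edges`` are the removed true edges
    and ``neg_edges`` an equal number of non-edges of the original graph.
    """

    train_graph: AttributedGraph
    pos_edges: np.ndarray
    neg_edges: np.ndarray


def link_prediction_split(G: AttributedGraph, frac: float = 0.5, seed: int = 0) -> LinkSplit:
    """Remove ``floor(frac * |E|)`` edges such that the residual graph stays
    connected.

    Edges are visited in a seeded random order and removed only if they are
    not bridges of the current residual graph. Negatives are drawn uniformly
    without replacement from the non-adjacent pairs of the *original* graph.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must be in (0, 1)")
    g = G.to_networkx()
    if G.n > 1 and not nx.is_connected(g):
        raise ValueError("link prediction split requires a connected graph")
    edges = G.edges()
    m = len(edges)
    target = int(np.floor(frac * m))
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    removed = []
    for k in order:
        if len(removed) == target:
            break
        u, v = map(int, edges[k])
        g.remove_edge(u, v)
        if nx.has_path(g, u, v):
            removed.append((u, v))
        else:  # bridge: putting it back keeps connectivity
            g.add_edge(u, v)
    if len(removed) < target:
        raise ValueError(
            f"cannot remove {target} edges while staying connected; achieved {len(removed)}"
        )
    pos = np.asarray(removed, dtype=np.int64)
    neg = _sample_non_edges(G, target, rng)
    train = AttributedGraph.from_edges(
        G.n, g.edges(), X=G.X, labels=G.labels, node_ids=list(G.node_ids)
    )
    assert nx.is_connected(train.to_networkx())
    return LinkSplit(train_graph=train, pos_edges=pos, neg_edges=neg)


def _sample_non_edges(G: AttributedGraph, count: int, rng) -> np.ndarray:
    """Uniform non-adjacent pairs (i < j, no self-pairs) without replacement."""
    n = G.n
    total_pairs = n * (n - 1) // 2
    n_non = total_pairs - G.num_edges
    if count > n_non:
        logger.warning(
            "only %d non-edge(s) available for %d requested negatives", n_non, count
        )
        count = n_non
    if count == 0:
        return np.empty((0, 2), dtype=np.int64)
    A = G.A
    chosen: set = set()
    # rejection sampling; non-edges dominate in sparse graphs
    while len(chosen) < count:
        draw = rng.integers(0, n, size=(max(4 * (count - len(chosen)), 16), 2))
        for i, j in draw:
            if i == j:
                continue
            e = (min(i, j), max(i, j))
            if e in chosen or A[e[0], e[1]]:
                continue
            chosen.add(e)
            if len(chosen) == count:
                break
    return np.asarray(sorted(chosen), dtype=np.int64)


def _cosine_scores(Y: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    u, v = Y[pairs[:, 0]], Y[pairs[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    denom = nu * nv
    zero = denom == 0
    if zero.any():
        logger.warning("%d pair(s) involve a zero embedding vector; score set to 0", zero.sum())
        denom[zero] = 1.0
    scores = (u * v).sum(axis=1) / denom
    scores[zero] = 0.0
    return scores


def auc_ranking(Y: Embedding | np.ndarray, split: LinkSplit) -> float:
    """Exact ranking AUC of removed edges vs sampled non-edges under the
    cosine score: P(score_pos > score_neg) + 0.5 * P(tie) over all pairs."""
    Y = Y.Y if isinstance(Y, Embedding) else np.asarray(Y, dtype=float)
    pos = _cosine_scores(Y, split.pos_edges)
    neg = _cosine_scores(Y, split.neg_edges)
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def node_classification_eval(
    Y: Embedding | np.ndarray,
    labels: dict | np.ndarray,
    train_frac: float = 0.3,
    repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Repeated random-split linear classification on the embeddings.

    Per repeat: sample ``train_frac`` of labeled nodes (resampling until every
    class appears in the training set), fit a linear max-margin (SVM)
    classifier with L2 regularization, and score Micro-F1 and Macro-F1 on the
    held-out nodes. Returns the means over repeats.
    """
    Y = Y.Y if isinstance(Y, Embedding) else np.asarray(Y, dtype=float)
    if isinstance(labels, dict):
        idx = np.asarray(sorted(labels), dtype=np.int64)
        y = np.asarray([labels[i] for i in idx])
    else:
        y = np.asarray(labels)
        idx = np.arange(len(y))
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("node classification needs at least two classes")
    rng = np.random.default_rng(seed)
    n_lab = len(idx)
    n_train = max(int(round(train_frac * n_lab)), classes.size)
    micro, macro = [], []
    for _ in range(repeats):
        for _attempt in range(100):
            perm = rng.permutation(n_lab)
            tr, te = perm[:n_train], perm[n_train:]
            if np.unique(y[tr]).size == classes.size and te.size:
                break
        else:
            raise ValueError("could not sample a training split covering every class")
        clf = LinearSVC(C=1.0, max_iter=10_000, random_state=0)
        clf.fit(Y[idx[tr]], y[tr])
        pred = clf.predict(Y[idx[te]])
        micro.append(f1_score(y[te], pred, average="micro"))
        macro.append(f1_score(y[te], pred, average="macro"))
    return {"micro_f1": float(np.mean(micro)), "macro_f1": float(np.mean(macro))}


def nmi(partition_a, partition_b) -> float:
    """Normalized mutual information (arithmetic-mean normalization) between
    two partitions of the same node set; 1 when identical up to relabeling."""
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same node set")
    if np.unique(a).size == 1 and np.unique(b).size == 1:
        return 1.0  # both degenerate single-cluster partitions agree trivially
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))
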