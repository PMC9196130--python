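"""Non-overlapping community detection: label propagation, two-phase modularity
optimization (multilevel/Louvain-style), and externally supplied assignments.

The multilevel routine is implemented here rather than delegated so that the
per-pass modularity trajectory can be logged and asserted monotone, and so a
fixed seed gives bit-for-bit reproducible partitions. Plug-in algorithms whose
internals are out of scope (e.g. Infomap) are consumed through
:func:`load_assignment`.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_io import AttributedGraph, GraphFormatError, _data_lines

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityAssignment",
    "lpa",
    "multilevel",
    "modularity",
    "load_assignment",
    "community_size_report",
]


@dataclass
class CommunityAssignment:
    """A hard partition of the n nodes into l communities.

    ``membership[i]`` is the community id (contiguous, 0..l-1) of node i; the
    one-hot indicator matrix ``C`` has ``C[i, m] = 1`` iff ``membership[i] == m``.
    """

    membership: np.ndarray
    l: int

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=np.int64)
        if self.membership.ndim != 1:
            raise ValueError("membership must be a 1-D vector")
        uniq = np.unique(self.membership)
        if self.l < 1 or not np.array_equal(uniq, np.arange(self.l)):
            raise ValueError("community ids must be contiguous 0..l-1")

    @property
    def n(self) -> int:
        return self.membership.size

    @property
    def C(self) -> np.ndarray:
        """One-hot n x l indicator matrix (each row sums to 1)."""
        C = np.zeros((self.n, self.l))
        C[np.arange(self.n), self.membership] = 1.0
        return C

    def sizes(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.l)

    @classmethod
    def from_labels(cls, labels) -> "CommunityAssignment":
        """Compact arbitrary hashable labels to contiguous ids by first appearance."""
        labels = list(labels)
        index: dict = {}
        member = np.empty(len(labels), dtype=np.int64)
        for i, lab in enumerate(labels):
            if lab not in index:
                index[lab] = len(index)
            member[i] = index[lab]
        return cls(membership=member, l=len(index))


def lpa(G: AttributedGraph, seed: int = 0, max_iter: int = 100) -> CommunityAssignment:
    """Asynchronous label propagation.

    Every node starts with a unique label. Nodes are visited in a fresh seeded
    random order each sweep; a node adopts the most frequent label among its
    neighbors, breaking ties uniformly at random. The sweep loop stops once
    every node's label is one of its neighborhood modes, or after ``max_iter``
    sweeps. Isolated nodes keep their own label.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if G.n < 1:
        raise ValueError("graph must have at least one node")
    rng = np.random.default_rng(seed)
    labels = np.arange(G.n)
    indptr, indices = G.A.indptr, G.A.indices
    order = np.arange(G.n)
    for _ in range(max_iter):
        rng.shuffle(order)
        changed = False
        for i in order:
            nbrs = indices[indptr[i] : indptr[i + 1]]
            if nbrs.size == 0:
                continue
            counts = Counter(labels[nbrs])
            top = max(counts.values())
            modes = [lab for lab, c in counts.items() if c == top]
            if labels[i] in modes:
                continue
            labels[i] = modes[rng.integers(len(modes))]
            changed = True
        if not changed and _all_modal(labels, indptr, indices):
            break
    return CommunityAssignment.from_labels(labels)


def _all_modal(labels, indptr, indices) -> bool:
    for i in range(labels.size):
        nbrs = indices[indptr[i] : indptr[i + 1]]
        if nbrs.size == 0:
            continue
        counts = Counter(labels[nbrs])
        if counts[labels[i]] < max(counts.values()):
            return False
    return True


def modularity(G: AttributedGraph, P: CommunityAssignment) -> float:
    """Newman modularity Q of a partition, in [-1/2, 1].

    Q = (1/2m) * sum_ij (a_ij - d_i d_j / 2m) * [same community].
    """
    if G.num_edges == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    comms = defaultdict(set)
    for i, m in enumerate(P.membership):
        comms[m].add(i)
    return nx.community.modularity(G.to_networkx(), comms.values())


def multilevel(G: AttributedGraph, seed: int = 0) -> CommunityAssignment:
    """Two-phase greedy modularity optimization (multilevel / Louvain scheme).

    Phase 1 sweeps nodes in a seeded random order, moving each to the
    neighboring community with the largest positive modularity gain, until a
    sweep makes no move. Phase 2 contracts communities to super-nodes
    (aggregating edge multiplicities as weights, intra-community edges as
    self-loops) and repeats. The pass loop stops when a full two-phase pass no
    longer increases modularity of the flattened partition.
    """
    if G.num_edges == 0:
        raise ValueError("multilevel requires at least one edge")
    rng = np.random.default_rng(seed)
    two_m = float(2 * G.num_edges)  # constant across levels

    # current contracted graph: adjacency dict u -> {v: w}, self-loops allowed
    adj: list[dict] = [dict() for _ in range(G.n)]
    for i, j in G.edges():
        adj[i][j] = adj[i].get(j, 0.0) + 1.0
        adj[j][i] = adj[j].get(i, 0.0) + 1.0
    node_to_orig: list[list[int]] = [[i] for i in range(G.n)]
    membership = np.arange(G.n)

    prev_q = _partition_modularity_flat(G, membership)
    logger.info("multilevel: singleton partition Q=%.6f", prev_q)
    while True:
        comm = _phase1(adj, rng, two_m)
        # flatten onto original nodes
        for u, groups in enumerate(node_to_orig):
            for orig in groups:
                membership[orig] = comm[u]
        membership = CommunityAssignment.from_labels(membership).membership
        q = _partition_modularity_flat(G, membership)
        logger.info("multilevel: pass Q=%.6f", q)
        assert q >= prev_q - 1e-12, "modularity decreased across a pass"
        if q <= prev_q + 1e-12:
            break
        prev_q = q
        adj, node_to_orig = _contract(adj, node_to_orig, comm)
        if len(adj) == 1:
            break
    return CommunityAssignment.from_labels(membership)


def _partition_modularity_flat(G, membership) -> float:
    P = CommunityAssignment.from_labels(membership)
    return modularity(G, P)


def _phase1(adj, rng, two_m):
    """Greedy local moving on a weighted graph; returns node -> community."""
    n = len(adj)
    comm = list(range(n))
    # k[u]: weighted degree incl. 2*self-loop; sigma_tot[c]: sum of k over c
    k = [sum(w for v, w in adj[u].items() if v != u) + 2 * adj[u].get(u, 0.0) for u in range(n)]
    sigma_tot = k.copy()
    order = np.arange(n)
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for u in order:
            cu = comm[u]
            # weight from u to each neighboring community (excluding self-loop)
            w_to: dict = defaultdict(float)
            for v, w in adj[u].items():
                if v != u:
                    w_to[comm[v]] += w
            sigma_tot[cu] -= k[u]
            best_c, best_gain = cu, 0.0
            base = w_to.get(cu, 0.0) - k[u] * sigma_tot[cu] / two_m
            for c, w in w_to.items():
                if c == cu:
                    continue
                # standard isolated-node move gain (constant terms cancel)
                gain = (w - k[u] * sigma_tot[c] / two_m) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            sigma_tot[best_c] += k[u]
            if best_c != cu:
                comm[u] = best_c
                improved = True
    return CommunityAssignment.from_labels(comm).membership


def _contract(adj, node_to_orig, comm):
    l = int(comm.max()) + 1
    new_adj: list[dict] = [dict() for _ in range(l)]
    for u, nbrs in enumerate(adj):
        cu = comm[u]
        for v, w in nbrs.items():
            cv = comm[v]
            if u == v:
                new_adj[cu][cu] = new_adj[cu].get(cu, 0.0) + w
            elif u < v:
                new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
                if cu != cv:
                    new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
    new_groups: list[list[int]] = [[] for _ in range(l)]
    for u, groups in enumerate(node_to_orig):
        new_groups[comm[u]].extend(groups)
    return new_adj, new_groups


def load_assignment(path, G: AttributedGraph) -> CommunityAssignment:
    """Load a two-column ``node community_token`` file (Infomap plug-in slot).

    Tokens are compacted to contiguous ids by first appearance. Every graph
    node must appear exactly once (a node listed twice with different tokens is
    an overlap error).
    """
    token: dict = {}
    for lineno, toks in _data_lines(path):
        if len(toks) < 2:
            raise GraphFormatError(f"{path}:{lineno}: expected 'node community'")
        try:
            i = G.index(toks[0])
        except KeyError:
            raise GraphFormatError(f"{path}:{lineno}: unknown node {toks[0]!r}") from None
        if i in token and token[i] != toks[1]:
            raise GraphFormatError(
                f"{path}:{lineno}: node {toks[0]!r} assigned to both "
                f"{token[i]!r} and {toks[1]!r} (overlapping assignment)"
            )
        token[i] = toks[1]
    missing = [G.node_ids[i] for i in range(G.n) if i not in token]
    if missing:
        raise GraphFormatError(f"{path}: missing assignment for node(s) {missing[:5]}")
    return CommunityAssignment.from_labels([token[i] for i in range(G.n)])


def community_size_report(P: CommunityAssignment) -> dict:
    """Summary of a partition: l, sizes, and fraction of nodes in the largest
    community (the diagnostic used to judge whether a detector over-merges)."""
    sizes = P.sizes()
    return {
        "l": P.l,
        "sizes": sizes.tolist(),
        "largest_fraction": float(sizes.max()) / P.n,
    }
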