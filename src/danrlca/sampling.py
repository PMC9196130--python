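"""Random-walk corpus generation and noise sampling for the skip-gram branch.

Walks are second-order (p, q)-biased in the node2vec sense; with the default
p = q = 1 they degenerate to uniform random walks. Negative (noise) nodes are
drawn from the degree^{3/4} unigram distribution through an alias table, so
each draw is O(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_io import AttributedGraph

__all__ = [
    "WalkConfig",
    "AliasTable",
    "generate_walks",
    "context_pairs",
    "NegativeSampler",
]


@dataclass
class WalkConfig:
    """Corpus parameters: r walks of length L per node, window b, |neg|
    negatives per observed pair, and node2vec bias parameters (p, q)."""

    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    num_negatives: int = 10
    p: float = 1.0
    q: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("walks_per_node", "walk_length", "window", "num_negatives"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


class AliasTable:
    """Walker's alias method: O(n) setup, O(1) sampling from a discrete
    distribution."""

    def __init__(self, probs):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise ValueError("probs must be a nonempty vector")
        if (probs < 0).any() or probs.sum() <= 0:
            raise ValueError("probs must be nonnegative with positive sum")
        self.probs = probs / probs.sum()
        n = probs.size
        scaled = self.probs * n
        self.accept = np.zeros(n)
        self.alias = np.zeros(n, dtype=np.int64)
        small = [i for i in range(n) if scaled[i] < 1.0]
        large = [i for i in range(n) if scaled[i] >= 1.0]
        while small and large:
            s, g = small.pop(), large.pop()
            self.accept[s] = scaled[s]
            self.alias[s] = g
            scaled[g] = scaled[g] - (1.0 - scaled[s])
            (small if scaled[g] < 1.0 else large).append(g)
        for rest in (small, large):
            for i in rest:
                self.accept[i] = 1.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        idx = rng.integers(self.probs.size, size=size)
        toss = rng.random(size)
        return np.where(toss < self.accept[idx], idx, self.alias[idx])


def _neighbor_lists(G: AttributedGraph) -> list[np.ndarray]:
    indptr, indices = G.A.indptr, G.A.indices
    return [indices[indptr[i] : indptr[i + 1]] for i in range(G.n)]


def generate_walks(G: AttributedGraph, cfg: WalkConfig) -> list[list[int]]:
    """Generate ``walks_per_node`` truncated walks of length <= ``walk_length``
    starting at every node.

    For p = q = 1 transitions are uniform over neighbors; otherwise the
    second-order bias reweights the step from t via v to x by 1/p when x = t,
    1 when x neighbors t, and 1/q otherwise, with per-(t, v) alias tables built
    lazily. Walks truncate at isolated nodes (length 1).
    """
    rng = np.random.default_rng(cfg.seed)
    nbrs = _neighbor_lists(G)
    uniform = cfg.p == 1.0 and cfg.q == 1.0
    nbr_sets = None if uniform else [set(a.tolist()) for a in nbrs]
    second_order: dict = {}
    walks = []
    for _ in range(cfg.walks_per_node):
        for start in range(G.n):
            walk = [start]
            while len(walk) < cfg.walk_length:
                cur = walk[-1]
                cand = nbrs[cur]
                if cand.size == 0:
                    break
                if uniform or len(walk) == 1:
                    nxt = cand[rng.integers(cand.size)]
                else:
                    prev = walk[-2]
                    key = (prev, cur)
                    table = second_order.get(key)
                    if table is None:
                        w = np.where(
                            cand == prev,
                            1.0 / cfg.p,
                            np.where([x in nbr_sets[prev] for x in cand], 1.0, 1.0 / cfg.q),
                        )
                        table = AliasTable(w)
                        second_order[key] = table
                    nxt = cand[table.draw(rng, 1)[0]]
                walk.append(int(nxt))
            walks.append(walk)
    return walks


def context_pairs(walks, window: int) -> np.ndarray:
    """All ordered (center, context) pairs within ``window`` positions in each
    walk, as an (m, 2) int array."""
    if window < 1:
        raise ValueError("window must be >= 1")
    pairs = []
    for walk in walks:
        L = len(walk)
        for i in range(L):
            lo, hi = max(0, i - window), min(L, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((walk[i], walk[j]))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


class NegativeSampler:
    """Noise-node sampler with P(v) proportional to degree(v)^{3/4}."""

    def __init__(self, degrees):
        degrees = np.asarray(degrees, dtype=float)
        if (degrees < 0).any():
            raise ValueError("degrees must be nonnegative")
        if degrees.sum() == 0:
            raise ValueError("all degrees are zero: noise distribution undefined")
        self.probs = degrees**0.75
        self.probs /= self.probs.sum()
        self._table = AliasTable(self.probs)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """i.i.d. noise nodes; not excluded from true contexts (pure noise)."""
        return self._table.draw(rng, size)


def negative_sampler(degrees, num: int, seed: int = 0) -> np.ndarray:
    """Draw ``num`` noise nodes from the degree^{3/4} distribution."""
    rng = np.random.default_rng(seed)
    return NegativeSampler(degrees).draw(rng, num)


def write_walks(walks, path) -> None:
    """Dump a walk corpus, one space-separated walk per line."""
    with open(path, "w") as fh:
        for walk in walks:
            fh.write(" ".join(map(str, walk)) + "\n")
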