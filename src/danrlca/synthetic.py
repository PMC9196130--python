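"""Synthetic attributed graphs with planted communities.

The generator is a balanced stochastic block model whose binary node
attributes are correlated with the planted blocks: each block owns an equal
share of the attribute columns, and a node switches on its own block's
attributes with probability ``attr_signal`` and any other attribute with
probability ``attr_noise``. This emulates assortative community structure
with community-aligned semantics (homophily) at a scale where every pipeline
stage is testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import CommunityAssignment
from .graph_io import AttributedGraph

__all__ = ["SBMSpec", "attributed_sbm", "toy_fixture", "TOY_NAMES"]


@dataclass
class SBMSpec:
    """Planted-partition settings: n nodes in ``num_blocks`` balanced blocks,
    within/between edge probabilities p_in > p_out, and f block-correlated
    binary attributes."""

    n: int = 300
    num_blocks: int = 3
    p_in: float = 0.1
    p_out: float = 0.005
    f: int = 60
    attr_signal: float = 0.3
    attr_noise: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n < self.num_blocks or self.num_blocks < 1:
            raise ValueError("need n >= num_blocks >= 1")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not (0 <= self.attr_noise < self.attr_signal <= 1):
            raise ValueError("require 0 <= attr_noise < attr_signal <= 1")
        if self.f < 0:
            raise ValueError("f must be nonnegative")


def attributed_sbm(spec: SBMSpec) -> tuple[AttributedGraph, CommunityAssignment]:
    """Sample a graph and its planted ground-truth assignment.

    Blocks are balanced (remainder nodes join the last block); every unordered
    within-block pair is an edge with probability p_in, between-block with
    p_out. Attribute columns are split evenly among blocks (remainder columns
    belong to no block and fire at the noise rate). Node labels are the block
    ids.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.n // spec.num_blocks
    blocks = np.repeat(np.arange(spec.num_blocks), base)
    blocks = np.concatenate([blocks, np.full(spec.n - blocks.size, spec.num_blocks - 1)])

    iu, ju = np.triu_indices(spec.n, k=1)
    p = np.where(blocks[iu] == blocks[ju], spec.p_in, spec.p_out)
    keep = rng.random(p.size) < p
    edges = np.column_stack([iu[keep], ju[keep]])

    X = None
    if spec.f > 0:
        per = spec.f // spec.num_blocks
        col_block = np.full(spec.f, -1)
        col_block[: per * spec.num_blocks] = np.repeat(np.arange(spec.num_blocks), per)
        own = blocks[:, None] == col_block[None, :]
        prob = np.where(own, spec.attr_signal, spec.attr_noise)
        X = (rng.random((spec.n, spec.f)) < prob).astype(float)

    labels = {i: int(blocks[i]) for i in range(spec.n)}
    G = AttributedGraph.from_edges(spec.n, edges, X=X, labels=labels)
    return G, CommunityAssignment(membership=blocks, l=spec.num_blocks)


def _edges_two_triangles():
    return 6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]


def _edges_barbell():
    # two K4 cliques joined by a single bridge 3-4
    cliques = [(i, j) for a in (0, 4) for i in range(a, a + 4) for j in range(i + 1, a + 4)]
    return 8, cliques + [(3, 4)]


def _edges_k4():
    return 4, [(i, j) for i in range(4) for j in range(i + 1, 4)]


def _edges_cycle6():
    return 6, [(i, (i + 1) % 6) for i in range(6)]


def _edges_star():
    return 6, [(0, i) for i in range(1, 6)]


_TOYS = {
    "two_triangles": _edges_two_triangles,
    "barbell": _edges_barbell,
    "k4": _edges_k4,
    "cycle6": _edges_cycle6,
    "star": _edges_star,
}

TOY_NAMES = tuple(_TOYS)


def toy_fixture(name: str) -> AttributedGraph:
    """Deterministic hand-specified graphs used throughout the unit tests."""
    try:
        n, edges = _TOYS[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {TOY_NAMES}") from None
    return AttributedGraph.from_edges(n, edges)
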