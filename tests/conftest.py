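import numpy as np
import pytest

from danrlca import AttributedGraph, toy_fixture


@pytest.fixture
def two_triangles():
    return toy_fixture("two_triangles")


@pytest.fixture
def k4():
    return toy_fixture("k4")


@pytest.fixture
def cycle6():
    return toy_fixture("cycle6")


@pytest.fixture
def path2():
    """A single edge 0-1."""
    return AttributedGraph.from_edges(2, [(0, 1)])


@pytest.fixture
def triangle_plus_isolate():
    """A triangle 0-1-2 plus the isolated node 3."""
    return AttributedGraph.from_edges(4, [(0, 1), (1, 2), (0, 2)])


def brute_force_modularity(G: AttributedGraph, membership) -> float:
    """Double loop over ordered node pairs: Q = (1/2m) sum_ij (a_ij - d_i d_j / 2m) delta."""
    A = G.A.toarray()
    deg = A.sum(axis=1)
    two_m = A.sum()
    q = 0.0
    for i in range(G.n):
        for j in range(G.n):
            if membership[i] == membership[j]:
                q += A[i, j] - deg[i] * deg[j] / two_m
    return q / two_m


def brute_force_cosine(M) -> np.ndarray:
    """Per-pair cosine with the zero-row-is-zero convention."""
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ni, nj = np.linalg.norm(M[i]), np.linalg.norm(M[j])
            if ni > 0 and nj > 0:
                S[i, j] = M[i] @ M[j] / (ni * nj)
    return S


def brute_force_auc(pos_scores, neg_scores) -> float:
    """Pair-counting oracle: wins + half-ties over all pos x neg pairs."""
    wins = ties = 0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


def brute_force_context_pairs(walks, window):
    pairs = []
    for walk in walks:
        for i, w in enumerate(walk):
            for j in range(len(walk)):
                if j != i and abs(j - i) <= window:
                    pairs.append((w, walk[j]))
    return pairs
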