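"""Plain-text I/O for attributed graphs, labels, community files and embeddings.

All on-disk formats are whitespace-separated text:

* edge list — two node tokens per line (``u v``), undirected, unweighted;
* attribute file — triplets ``node attr value`` or dense rows ``node v1 .. vf``;
* label file — ``node label``;
* embedding file — word2vec text format: header ``n d``, then ``id x1 .. xd``.

External node identifiers are arbitrary strings; they are mapped to dense
0-based internal indices in first-appearance order, and the mapping is kept on
the :class:`AttributedGraph` so outputs can be written back in external ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "AttributedGraph",
    "Embedding",
    "GraphFormatError",
    "read_edge_list",
    "read_attribute_matrix",
    "read_labels",
    "write_embedding",
    "read_embedding",
]


class GraphFormatError(ValueError):
    """Raised when an input file violates the expected text format."""


@dataclass
class AttributedGraph:
    """An undirected, unweighted graph with optional node attributes and labels.

    Attributes
    ----------
    n : int
        Number of nodes.
    node_ids : list of str
        External identifiers in internal-index order (first appearance).
    A : scipy.sparse.csr_matrix
        Symmetric binary adjacency, zero diagonal, shape ``(n, n)``.
    X : ndarray of shape (n, f) or None
        Nonnegative node-attribute matrix; ``None`` in structure-only mode.
    labels : dict[int, int] or None
        Internal node index -> label id, for the labeled subset.
    """

    n: int
    node_ids: list
    A: sp.csr_matrix
    X: np.ndarray | None = None
    labels: dict | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {v: i for i, v in enumerate(self.node_ids)}
        self.validate()

    def validate(self) -> None:
        A = self.A
        if A.shape != (self.n, self.n):
            raise ValueError(f"adjacency shape {A.shape} != ({self.n}, {self.n})")
        if (A != A.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")
        if A.nnz and not np.isin(A.data, (0, 1)).all():
            raise ValueError("adjacency entries must be binary")
        if self.X is not None:
            if self.X.shape[0] != self.n:
                raise ValueError("attribute matrix row count must equal n")
            if (self.X < 0).any():
                raise ValueError("attributes must be nonnegative")
        if self.labels is not None:
            bad = [i for i in self.labels if not (0 <= i < self.n)]
            if bad:
                raise ValueError(f"labeled ids not in graph: {bad[:5]}")

    def index(self, node_id) -> int:
        """Internal index of an external node id."""
        return self._index[node_id]

    @property
    def num_edges(self) -> int:
        return self.A.nnz // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel().astype(np.int64)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (m, 2) array of internal indices, i < j."""
        coo = sp.triu(self.A, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges()))
        return g

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges,
        X: np.ndarray | None = None,
        labels: dict | None = None,
        node_ids: list | None = None,
    ) -> "AttributedGraph":
        """Build a graph from an iterable of (i, j) internal-index pairs."""
        edges = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
        keep = edges[:, 0] != edges[:, 1]
        edges = edges[keep]
        if len(edges):
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            edges = np.unique(np.column_stack([lo, hi]), axis=0)
        data = np.ones(2 * len(edges))
        rows = np.concatenate([edges[:, 0], edges[:, 1]])
        cols = np.concatenate([edges[:, 1], edges[:, 0]])
        A = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        A.data[:] = 1  # collapse any accidental duplicates
        if node_ids is None:
            node_ids = [str(i) for i in range(n)]
        return cls(n=n, node_ids=node_ids, A=A, X=X, labels=labels)


@dataclass
class Embedding:
    """A learned node representation matrix Y of shape (n, d), d << n."""

    Y: np.ndarray
    node_ids: list | None = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("embedding must be a 2-D matrix")
        if not np.isfinite(self.Y).all():
            raise ValueError("embedding contains non-finite entries")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def d(self) -> int:
        return self.Y.shape[1]


def _data_lines(path):
    """Yield (lineno, tokens) for non-blank, non-comment lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_edge_list(path) -> AttributedGraph:
    """Read an undirected simple graph from a two-column edge list.

    Duplicate edges and self-loops are dropped (counts logged). Node order is
    first-appearance order and is stable across reads.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    index: dict = {}
    node_ids: list = []
    edges = set()
    n_dup = n_loop = 0
    seen_any = False
    for lineno, toks in _data_lines(path):
        seen_any = True
        if len(toks) < 2:
            raise GraphFormatError(f"{path}:{lineno}: expected two node tokens, got {toks!r}")
        u, v = toks[0], toks[1]
        for t in (u, v):
            if t not in index:
                index[t] = len(node_ids)
                node_ids.append(t)
        iu, iv = index[u], index[v]
        if iu == iv:
            n_loop += 1
            continue
        e = (min(iu, iv), max(iu, iv))
        if e in edges:
            n_dup += 1
        else:
            edges.add(e)
    if not seen_any:
        raise GraphFormatError(f"{path}: empty edge list")
    if n_dup or n_loop:
        logger.info("%s: dropped %d duplicate edge(s), %d self-loop(s)", path, n_dup, n_loop)
    return AttributedGraph.from_edges(len(node_ids), sorted(edges), node_ids=node_ids)


def read_attribute_matrix(path, graph: AttributedGraph) -> np.ndarray | None:
    """Read node attributes for ``graph``; returns ``None`` for an empty file.

    Accepts sparse triplet lines ``node attr value`` (attr is a 0-based column
    index) or dense lines ``node v1 .. vf`` (constant width > 3 columns, or any
    width if every line has the same number of tokens != 3). Unlisted entries
    are zero. Negative values and unknown node ids are errors.
    """
    rows = list(_data_lines(path))
    if not rows:
        return None
    widths = {len(t) for _, t in rows}
    triplet = widths == {3} and all(_is_int(t[1]) for _, t in rows)
    if triplet:
        f = max(int(t[1]) for _, t in rows) + 1
        X = np.zeros((graph.n, f))
        for lineno, (node, attr, val) in ((ln, t) for ln, t in rows):
            i = _node_index(graph, node, path, lineno)
            v = float(val)
            if v < 0:
                raise GraphFormatError(f"{path}:{lineno}: negative attribute value {v}")
            X[i, int(attr)] = v
    else:
        if len(widths) != 1:
            raise GraphFormatError(f"{path}: inconsistent dense row widths {sorted(widths)}")
        f = widths.pop() - 1
        X = np.zeros((graph.n, f))
        for lineno, toks in rows:
            i = _node_index(graph, toks[0], path, lineno)
            vals = np.array([float(x) for x in toks[1:]])
            if (vals < 0).any():
                raise GraphFormatError(f"{path}:{lineno}: negative attribute value")
            X[i] = vals
    return X


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def _node_index(graph, token, path, lineno):
    try:
        return graph.index(token)
    except KeyError:
        raise GraphFormatError(f"{path}:{lineno}: node id {token!r} not in graph") from None


def read_labels(path, graph: AttributedGraph) -> dict:
    """Read a two-column ``node label`` file into an index -> label-id map."""
    labels: dict = {}
    label_index: dict = {}
    for lineno, toks in _data_lines(path):
        if len(toks) < 2:
            raise GraphFormatError(f"{path}:{lineno}: expected 'node label'")
        i = _node_index(graph, toks[0], path, lineno)
        lab = toks[1]
        if lab not in label_index:
            label_index[lab] = len(label_index)
        labels[i] = label_index[lab]
    return labels


def write_embedding(emb: Embedding, path) -> None:
    """Write Y in word2vec text format: header ``n d``, then ``id x1 .. xd``."""
    n, d = emb.Y.shape
    if d == 0:
        raise ValueError("cannot write an embedding with d=0")
    if not np.isfinite(emb.Y).all():
        raise ValueError("embedding contains non-finite entries")
    ids = emb.node_ids if emb.node_ids is not None else [str(i) for i in range(n)]
    with open(path, "w") as fh:
        fh.write(f"{n} {d}\n")
        for i in range(n):
            row = " ".join(repr(float(x)) for x in emb.Y[i])
            fh.write(f"{ids[i]} {row}\n")


def read_embedding(path) -> Embedding:
    """Read an embedding written by :func:`write_embedding`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise GraphFormatError(f"{path}: malformed header {header!r}")
        n, d = int(header[0]), int(header[1])
        Y = np.empty((n, d))
        ids = []
        for i in range(n):
            toks = fh.readline().split()
            if len(toks) != d + 1:
                raise GraphFormatError(f"{path}: row {i} has {len(toks) - 1} values, expected {d}")
            ids.append(toks[0])
            Y[i] = [float(x) for x in toks[1:]]
    return Embedding(Y=Y, node_ids=ids)
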