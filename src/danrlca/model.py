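"""The coupled embedding model and its training loop.

Two branches share one encoder:

* a **neighborhood-enhancement autoencoder** reconstructs rows of the
  reconstructed adjacency R through a mirrored tanh tower, with squared error
  up-weighted by chi on the nonzero support of R (second-order proximity);
* a **community-aware skip-gram** treats the encoder output y_i as the center
  representation of node i and scores (center, context) pairs from random
  walks against degree^{3/4} noise nodes through a free context matrix H
  (high-order proximity).

The joint objective is ``L = L_sg + alpha * L_ae + gamma * L_reg`` where
L_reg is the squared Frobenius norm of the encoder and decoder weight
matrices (halved). Training alternates skip-gram and autoencoder mini-batches
with a shared Adam optimizer; gradients are derived analytically (closed-form
backprop through the tanh towers) and validated against finite differences in
the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .community import CommunityAssignment, lpa, multilevel
from .graph_io import AttributedGraph, Embedding
from .preprocess import build_reconstruction
from .sampling import NegativeSampler, WalkConfig, context_pairs, generate_walks

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "TrainConfig",
    "DANRLCA",
    "init_params",
    "encode",
    "decode",
    "autoencoder_loss",
    "sgns_loss",
    "reg_loss",
    "total_loss",
    "train",
]


@dataclass
class ModelParams:
    """All trainables: encoder/decoder weights and biases plus the skip-gram
    context matrix H (one d-vector per node)."""

    enc_W: list
    enc_b: list
    dec_W: list
    dec_b: list
    H: np.ndarray
    layer_sizes: list = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.layer_sizes[-1]

    def flat(self) -> list:
        """All parameter arrays in a fixed order (for optimizers/grad checks)."""
        return [*self.enc_W, *self.enc_b, *self.dec_W, *self.dec_b, self.H]


@dataclass
class TrainConfig:
    """Optimization settings for the coupled objective."""

    variant: str = "csm"
    alpha: float = 1.0
    gamma: float = 1e-4
    chi: float = 10.0
    eta: float = 1.0
    psi: float = 1.0
    phi: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 64
    sg_batch_size: int = 1024
    epochs: int = 50
    ae_passes: int = 5
    tol: float = 1e-5
    patience: int = 5
    seed: int = 0
    walk: WalkConfig = field(default_factory=WalkConfig)

    def __post_init__(self):
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def init_params(layer_sizes, n_nodes: int, seed: int = 0) -> ModelParams:
    """Glorot-uniform initialization for a mirrored tower.

    ``layer_sizes`` runs from the input width down to the code dimension d and
    must be strictly decreasing; the decoder mirrors it.
    """
    sizes = list(layer_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least input and code sizes")
    if any(a <= b for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"layer sizes must strictly decrease to d, got {sizes}")
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    enc_W = [glorot(a, b) for a, b in zip(sizes, sizes[1:])]
    enc_b = [np.zeros(b) for b in sizes[1:]]
    mirror = sizes[::-1]
    dec_W = [glorot(a, b) for a, b in zip(mirror, mirror[1:])]
    dec_b = [np.zeros(b) for b in mirror[1:]]
    H = rng.uniform(-0.05, 0.05, size=(n_nodes, sizes[-1]))
    return ModelParams(enc_W, enc_b, dec_W, dec_b, H, layer_sizes=sizes)


def _forward(x, Ws, bs):
    """tanh MLP forward pass; returns all activations (input first)."""
    acts = [np.atleast_2d(np.asarray(x, dtype=float))]
    for W, b in zip(Ws, bs):
        acts.append(np.tanh(acts[-1] @ W + b))
    return acts


def _backward(acts, Ws, grad_out):
    """Backprop ``grad_out`` (dL/d acts[-1]) through a tanh MLP.

    Returns (dWs, dbs, grad wrt input).
    """
    dWs, dbs = [], []
    g = grad_out
    for k in range(len(Ws) - 1, -1, -1):
        da = g * (1.0 - acts[k + 1] ** 2)
        dWs.insert(0, acts[k].T @ da)
        dbs.insert(0, da.sum(axis=0))
        g = da @ Ws[k].T
    return dWs, dbs, g


def encode(R_rows, params: ModelParams) -> np.ndarray:
    """Encoder output y^(K) for one row of R or a batch of rows."""
    x = np.asarray(R_rows, dtype=float)
    single = x.ndim == 1
    if np.atleast_2d(x).shape[1] != params.layer_sizes[0]:
        raise ValueError(
            f"input width {np.atleast_2d(x).shape[1]} != encoder input {params.layer_sizes[0]}"
        )
    out = _forward(x, params.enc_W, params.enc_b)[-1]
    return out[0] if single else out


def decode(codes, params: ModelParams) -> np.ndarray:
    """Mirrored decoder: code(s) of width d back to reconstruction(s) of the
    input width."""
    y = np.asarray(codes, dtype=float)
    single = y.ndim == 1
    if np.atleast_2d(y).shape[1] != params.d:
        raise ValueError(f"code width {np.atleast_2d(y).shape[1]} != d={params.d}")
    out = _forward(y, params.dec_W, params.dec_b)[-1]
    return out[0] if single else out


def autoencoder_loss(R, R_hat, B) -> float:
    """Hadamard-weighted squared reconstruction error
    ``sum_i || (R_hat_i - R_i) * b_i ||^2``; with chi -> 1 this is the plain
    squared error."""
    R, R_hat, B = (np.asarray(m, dtype=float) for m in (R, R_hat, B))
    if not (R.shape == R_hat.shape == B.shape):
        raise ValueError("R, R_hat and B must share a shape")
    return float((((R_hat - R) * B) ** 2).sum())


def _log_sigmoid(x):
    # -softplus(-x), stable for large |x|
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def sgns_loss(center_codes, pos_contexts, neg_draws, H) -> float:
    """Negative-sampling skip-gram loss over observed (center, context) pairs.

    ``center_codes`` are the encoder outputs y of the pair centers (m, d);
    ``pos_contexts`` (m,) and ``neg_draws`` (m, |neg|) index rows of H.
    loss = -sum [ log sigma(h_ctx . y) + sum_s log sigma(-h_s . y) ].
    """
    Y = np.atleast_2d(np.asarray(center_codes, dtype=float))
    pos = np.asarray(pos_contexts, dtype=np.int64).ravel()
    neg = np.asarray(neg_draws, dtype=np.int64).reshape(len(pos), -1)
    s_pos = (H[pos] * Y).sum(axis=1)
    s_neg = np.einsum("mkd,md->mk", H[neg], Y)
    return float(-(_log_sigmoid(s_pos).sum() + _log_sigmoid(-s_neg).sum()))


def reg_loss(params: ModelParams) -> float:
    """(1/2) sum of squared Frobenius norms of encoder and decoder weight
    matrices; biases and H are not penalized."""
    return 0.5 * sum(float((W**2).sum()) for W in params.enc_W + params.dec_W)


def total_loss(sg: float, ae: float, reg: float, alpha: float, gamma: float) -> float:
    """Joint objective L = L_sg + alpha * L_ae + gamma * L_reg."""
    return float(sg + alpha * ae + gamma * reg)


# ---------------------------------------------------------------------------
# analytic gradients


def ae_gradients(params: ModelParams, R_batch, B_batch):
    """Loss and gradients of the weighted reconstruction error on a row batch.

    Returns (loss, grads) where grads holds dL/d(enc_W, enc_b, dec_W, dec_b).
    """
    R_batch = np.atleast_2d(np.asarray(R_batch, dtype=float))
    B_batch = np.atleast_2d(np.asarray(B_batch, dtype=float))
    enc_acts = _forward(R_batch, params.enc_W, params.enc_b)
    dec_acts = _forward(enc_acts[-1], params.dec_W, params.dec_b)
    R_hat = dec_acts[-1]
    err = (R_hat - R_batch) * B_batch
    loss = float((err**2).sum())
    g_out = 2.0 * err * B_batch
    dec_dW, dec_db, g_code = _backward(dec_acts, params.dec_W, g_out)
    enc_dW, enc_db, _ = _backward(enc_acts, params.enc_W, g_code)
    return loss, {"enc_W": enc_dW, "enc_b": enc_db, "dec_W": dec_dW, "dec_b": dec_db}


def sg_gradients(params: ModelParams, R_rows, centers, contexts, negatives):
    """Loss and gradients of the skip-gram branch on a pair batch.

    ``R_rows`` is the full (row-normalized) R matrix; ``centers``/``contexts``
    are pair node indices and ``negatives`` is (m, |neg|) noise indices.
    Returns (loss, grads) with dL/d(enc_W, enc_b, H).
    """
    centers = np.asarray(centers, dtype=np.int64).ravel()
    contexts = np.asarray(contexts, dtype=np.int64).ravel()
    negatives = np.asarray(negatives, dtype=np.int64).reshape(len(centers), -1)
    # encode each distinct center once; pairs far outnumber nodes in a batch
    uniq, inv = np.unique(centers, return_inverse=True)
    enc_acts = _forward(R_rows[uniq], params.enc_W, params.enc_b)
    Y = enc_acts[-1][inv]
    H = params.H
    s_pos = (H[contexts] * Y).sum(axis=1)
    s_neg = np.einsum("mkd,md->mk", H[negatives], Y)
    loss = float(-(_log_sigmoid(s_pos).sum() + _log_sigmoid(-s_neg).sum()))

    from scipy.special import expit

    c_pos = expit(s_pos) - 1.0  # dL/ds_pos
    c_neg = expit(s_neg)  # dL/ds_neg
    gY = c_pos[:, None] * H[contexts] + np.einsum("mk,mkd->md", c_neg, H[negatives])
    dH = np.zeros_like(H)
    np.add.at(dH, contexts, c_pos[:, None] * Y)
    np.add.at(dH, negatives.ravel(), (c_neg[:, :, None] * Y[:, None, :]).reshape(-1, Y.shape[1]))
    gY_uniq = np.zeros_like(enc_acts[-1])
    np.add.at(gY_uniq, inv, gY)
    enc_dW, enc_db, _ = _backward(enc_acts, params.enc_W, gY_uniq)
    return loss, {"enc_W": enc_dW, "enc_b": enc_db, "H": dH}


class _Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, arrays, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.arrays = arrays
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            if g is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _normalize_rows(R: np.ndarray) -> np.ndarray:
    """Scale each row by its max |entry| so the tanh decoder can reach it
    (zero rows untouched)."""
    scale = np.abs(R).max(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return R / scale


def train(
    G: AttributedGraph,
    community: CommunityAssignment | None,
    cfg: TrainConfig,
    layer_sizes=None,
    return_state: bool = False,
):
    """Run the full alternating optimization and return the embedding.

    Builds (R, B) for ``cfg.variant``, generates the walk corpus, then per
    epoch interleaves skip-gram pair batches (updating encoder + H) with
    autoencoder row batches (updating encoder + decoder), both with the L2
    weight penalty. Stops early when the relative change of the epoch loss
    stays below ``cfg.tol`` for ``cfg.patience`` epochs. Returns encoder
    outputs for all rows of R.
    """
    recon, pen = build_reconstruction(
        G, community, variant=cfg.variant, eta=cfg.eta, psi=cfg.psi, phi=cfg.phi, chi=cfg.chi
    )
    R = _normalize_rows(recon.R)
    logger.info("rows of R max-normalized before training")
    B = pen.B
    if layer_sizes is None:
        hidden = [h for h in (1000, 500) if 128 < h < G.n]
        layer_sizes = [G.n, *hidden, min(128, max(2, G.n // 2))]
    params = init_params(layer_sizes, G.n, seed=cfg.seed)

    walks = generate_walks(G, cfg.walk)
    pairs = context_pairs(walks, cfg.walk.window)
    if len(pairs) == 0:
        raise ValueError("empty walk corpus: no context pairs to train on")
    sampler = NegativeSampler(G.degrees)
    rng = np.random.default_rng(cfg.seed + 1)

    arrays = params.flat()
    opt = _Adam(arrays, lr=cfg.learning_rate)
    nW = len(params.enc_W)
    nD = len(params.dec_W)

    def packed(enc_W=None, enc_b=None, dec_W=None, dec_b=None, H=None):
        """Arrange component grads into the flat() order, None elsewhere."""
        out = [None] * len(arrays)
        if enc_W is not None:
            out[:nW] = enc_W
        if enc_b is not None:
            out[nW : 2 * nW] = enc_b
        if dec_W is not None:
            out[2 * nW : 2 * nW + nD] = dec_W
        if dec_b is not None:
            out[2 * nW + nD : 2 * nW + 2 * nD] = dec_b
        if H is not None:
            out[-1] = H
        return out

    def add_reg(grads_W, Ws):
        return [g + cfg.gamma * W for g, W in zip(grads_W, Ws)]

    row_order = np.arange(G.n)
    history = []
    stall = 0
    prev = None
    for epoch in range(cfg.epochs):
        rng.shuffle(pairs)
        rng.shuffle(row_order)
        sg_total = 0.0
        ae_total = 0.0
        n_row_batches = int(np.ceil(G.n / cfg.batch_size))
        row_batches = [
            row_order[k * cfg.batch_size : (k + 1) * cfg.batch_size] for k in range(n_row_batches)
        ]
        n_sg_batches = int(np.ceil(len(pairs) / cfg.sg_batch_size))
        # interleave ae_passes full autoencoder sweeps evenly across the
        # skip-gram batches of the epoch
        n_ae = min(cfg.ae_passes * n_row_batches, max(n_sg_batches, n_row_batches))
        ae_slots = set(np.linspace(0, max(n_sg_batches - 1, 0), n_ae, dtype=int).tolist())
        rb = 0
        for bi, start in enumerate(range(0, len(pairs), cfg.sg_batch_size)):
            batch = pairs[start : start + cfg.sg_batch_size]
            negs = sampler.draw(rng, batch.shape[0] * cfg.walk.num_negatives).reshape(
                batch.shape[0], -1
            )
            sg_l, sg_g = sg_gradients(params, R, batch[:, 0], batch[:, 1], negs)
            sg_total += sg_l
            opt.step(
                packed(enc_W=add_reg(sg_g["enc_W"], params.enc_W), enc_b=sg_g["enc_b"], H=sg_g["H"])
            )
            if bi not in ae_slots:
                continue
            idx = row_batches[rb % n_row_batches]
            rb += 1
            ae_l, ae_g = ae_gradients(params, R[idx], B[idx])
            ae_total += ae_l
            opt.step(
                packed(
                    enc_W=add_reg([cfg.alpha * g for g in ae_g["enc_W"]], params.enc_W),
                    enc_b=[cfg.alpha * g for g in ae_g["enc_b"]],
                    dec_W=add_reg([cfg.alpha * g for g in ae_g["dec_W"]], params.dec_W),
                    dec_b=[cfg.alpha * g for g in ae_g["dec_b"]],
                )
            )
        epoch_loss = total_loss(
            sg_total, ae_total * n_row_batches / max(rb, 1), reg_loss(params), cfg.alpha, cfg.gamma
        )
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: sg={sg_total}, ae={ae_total}"
            )
        history.append(epoch_loss)
        logger.info("epoch %d: loss %.4f (sg %.4f, ae %.4f)", epoch, epoch_loss, sg_total, ae_total)
        if prev is not None and abs(prev - epoch_loss) <= cfg.tol * max(abs(prev), 1.0):
            stall += 1
            if stall >= cfg.patience:
                logger.info("early stop at epoch %d", epoch)
                break
        else:
            stall = 0
        prev = epoch_loss

    Y = encode(R, params)
    emb = Embedding(Y=Y, node_ids=list(G.node_ids))
    if return_state:
        return emb, params, {"history": history, "R": R, "B": B}
    return emb


class DANRLCA(BaseEstimator):
    """Community-aware attributed network embedding estimator.

    Couples a neighborhood-enhancement autoencoder over the reconstructed
    adjacency R with a community-aware skip-gram over random-walk contexts,
    sharing one encoder. ``fit`` accepts an :class:`AttributedGraph` and an
    optional precomputed :class:`CommunityAssignment`; without one the
    detector named by ``community_method`` is run first.

    Parameters
    ----------
    variant : {"csm", "am"}
        How community information enters R: as a separately weighted
        community-similarity term (CSM) or as extra attribute columns (AM).
    dim : int
        Embedding dimension d.
    hidden_layers : tuple of int or None
        Encoder tower between the input and d; ``None`` picks 1000-500
        truncated to the input width.
    community_method : {"multilevel", "lpa", "none"}
        Detector used when no assignment is passed to ``fit``.
    eta, psi, phi : float
        Mixing weights of adjacency, attribute similarity and community
        similarity in R.
    chi : float
        Reconstruction penalty on nonzero entries of R (> 1).
    alpha, gamma : float
        Weights of the autoencoder branch and of the L2 regularizer.
    walks_per_node, walk_length, window, num_negatives, p, q :
        Walk-corpus settings of the skip-gram branch.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, dim)
        Learned node representations (encoder outputs).
    community_ : CommunityAssignment
        Assignment used during fitting (None in no-community mode).
    loss_history_ : list of float
        Joint objective per epoch.
    """

    def __init__(
        self,
        variant: str = "csm",
        dim: int = 128,
        hidden_layers=None,
        community_method: str = "multilevel",
        eta: float = 1.0,
        psi: float = 1.0,
        phi: float = 1.0,
        chi: float = 10.0,
        alpha: float = 1.0,
        gamma: float = 1e-4,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        sg_batch_size: int = 1024,
        epochs: int = 50,
        ae_passes: int = 5,
        walks_per_node: int = 10,
        walk_length: int = 80,
        window: int = 10,
        num_negatives: int = 10,
        p: float = 1.0,
        q: float = 1.0,
        tol: float = 1e-5,
        patience: int = 5,
        seed: int = 0,
    ):
        self.variant = variant
        self.dim = dim
        self.hidden_layers = hidden_layers
        self.community_method = community_method
        self.eta = eta
        self.psi = psi
        self.phi = phi
        self.chi = chi
        self.alpha = alpha
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.sg_batch_size = sg_batch_size
        self.epochs = epochs
        self.ae_passes = ae_passes
        self.walks_per_node = walks_per_node
        self.walk_length = walk_length
        self.window = window
        self.num_negatives = num_negatives
        self.p = p
        self.q = q
        self.tol = tol
        self.patience = patience
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            variant=self.variant,
            alpha=self.alpha,
            gamma=self.gamma,
            chi=self.chi,
            eta=self.eta,
            psi=self.psi,
            phi=self.phi,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            sg_batch_size=self.sg_batch_size,
            epochs=self.epochs,
            ae_passes=self.ae_passes,
            tol=self.tol,
            patience=self.patience,
            seed=self.seed,
            walk=WalkConfig(
                walks_per_node=self.walks_per_node,
                walk_length=self.walk_length,
                window=self.window,
                num_negatives=self.num_negatives,
                p=self.p,
                q=self.q,
                seed=self.seed,
            ),
        )

    def _layer_sizes(self, n: int) -> list:
        if self.dim >= n:
            raise ValueError(f"dim={self.dim} must be smaller than n={n}")
        if self.hidden_layers is not None:
            hidden = list(self.hidden_layers)
        else:
            hidden = [h for h in (1000, 500) if self.dim < h < n]
        return [n, *hidden, self.dim]

    def fit(self, G: AttributedGraph, community: CommunityAssignment | None = None):
        """Learn embeddings for every node of ``G``."""
        if community is None:
            method = (self.community_method or "none").lower()
            if method == "lpa":
                community = lpa(G, seed=self.seed)
            elif method == "multilevel":
                community = multilevel(G, seed=self.seed)
            elif method == "none":
                community = None
            else:
                raise ValueError(f"unknown community_method {self.community_method!r}")
        emb, params, state = train(
            G,
            community,
            self._train_config(),
            layer_sizes=self._layer_sizes(G.n),
            return_state=True,
        )
        self.embedding_ = emb.Y
        self.node_ids_ = list(G.node_ids)
        self.community_ = community
        self.params_ = params
        self.loss_history_ = state["history"]
        return self

    def fit_transform(self, G: AttributedGraph, community=None) -> np.ndarray:
        return self.fit(G, community).embedding_

    def transform(self, G: AttributedGraph = None) -> np.ndarray:
        """Return the fitted embedding (transductive model: new nodes are not
        supported)."""
        if not hasattr(self, "embedding_"):
            raise RuntimeError("estimator is not fitted")
        return self.embedding_
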