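"""Similarity matrices and the reconstructed adjacency R fed to the autoencoder.

Two variants blend structure with node semantics:

* **AM** — the community indicator matrix C is appended to the attribute
  matrix X as extra columns (W = [X | C]); R = eta*A + psi*cos(W).
* **CSM** — attribute and community similarities enter as separate terms with
  their own weights: R = eta*A + psi*cos(X) + phi*cos(C).

Reconstructing rows of R pushes nodes with similar (attribute- and
community-augmented) neighborhoods toward similar codes, which is how the
autoencoder branch preserves second-order proximity. The penalty matrix B
up-weights the reconstruction error on nonzero entries of R so that observed
relations dominate the (overwhelmingly sparse) zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .community import CommunityAssignment
from .graph_io import AttributedGraph

__all__ = [
    "ReconstructedAdjacency",
    "PenaltyMatrix",
    "cosine_similarity_matrix",
    "concat_attributes_community",
    "reconstructed_adjacency_am",
    "reconstructed_adjacency_csm",
    "penalty_matrix",
    "build_reconstruction",
]

#: grid searched for the mixing weights when tuning
MIXING_GRID = (0.5, 1.0, 1.5, 2.0, 2.5)

#: entries of R with |r_ij| below this are treated as exact zeros in B
ZERO_TOL = 1e-12


@dataclass
class ReconstructedAdjacency:
    """R = eta*A + psi*S_attr (+ phi*S_comm), with its mixing weights."""

    R: np.ndarray
    eta: float
    psi: float
    phi: float = 0.0

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")
        if not np.isfinite(self.R).all():
            raise ValueError("R contains non-finite entries")


@dataclass
class PenaltyMatrix:
    """B with b_ij = chi where r_ij != 0 and 1 elsewhere; chi > 1."""

    B: np.ndarray
    chi: float


def cosine_similarity_matrix(M, top_k: int | None = None) -> np.ndarray:
    """Pairwise cosine similarity of the rows of M.

    Zero rows have zero similarity to everything, including themselves (an
    attribute-less node is similar to no one); nonzero rows have unit
    self-similarity. With ``top_k`` set, only the k largest off-diagonal
    entries per row are kept (symmetrized by max), a memory/noise reduction
    for large n; default keeps the dense matrix.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    # sklearn maps zero rows to zero after normalization, matching the
    # zero-row convention above
    S = _sk_cosine(M)
    if top_k is not None:
        n = S.shape[0]
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        off = S - np.diag(np.diag(S))
        keep = np.zeros_like(S, dtype=bool)
        idx = np.argsort(off, axis=1)[:, -top_k:]
        keep[np.arange(n)[:, None], idx] = True
        keep |= keep.T  # keep symmetry
        S = np.where(keep | np.eye(n, dtype=bool), S, 0.0)
    return S


def concat_attributes_community(X, C) -> np.ndarray:
    """W = [X | C]: attribute columns followed by community indicator columns.

    ``X`` may be ``None`` (structure-only mode), in which case W = C.
    """
    if X is None:
        if C is None:
            raise ValueError("nothing to merge: both X and C absent")
        return np.asarray(C, dtype=float)
    X = np.asarray(X, dtype=float)
    if C is None:
        return X
    C = np.asarray(C, dtype=float)
    if X.shape[0] != C.shape[0]:
        raise ValueError(f"row mismatch: X has {X.shape[0]} rows, C has {C.shape[0]}")
    if X.shape[1] + C.shape[1] == 0:
        raise ValueError("nothing to merge: zero total columns")
    return np.hstack([X, C])


def _check_square(n, *mats):
    for M in mats:
        if M is not None and M.shape != (n, n):
            raise ValueError(f"shape mismatch: expected ({n}, {n}), got {M.shape}")


def reconstructed_adjacency_am(A, W_S, eta: float, psi: float) -> ReconstructedAdjacency:
    """R = eta*A + psi*W_S (AM variant; community enters through W = [X | C])."""
    A = _dense(A)
    W_S = np.asarray(W_S, dtype=float)
    _check_square(A.shape[0], W_S)
    _check_weights(eta=eta, psi=psi)
    return ReconstructedAdjacency(R=eta * A + psi * W_S, eta=eta, psi=psi)


def reconstructed_adjacency_csm(
    A, X_S, C_S, eta: float, psi: float, phi: float
) -> ReconstructedAdjacency:
    """R = eta*A + psi*X_S + phi*C_S (CSM variant).

    ``X_S`` may be ``None`` in structure-only mode; the attribute term is then
    dropped.
    """
    A = _dense(A)
    C_S = np.asarray(C_S, dtype=float)
    X_S = None if X_S is None else np.asarray(X_S, dtype=float)
    _check_square(A.shape[0], X_S, C_S)
    _check_weights(eta=eta, psi=psi, phi=phi)
    R = eta * A + phi * C_S
    if X_S is not None:
        R = R + psi * X_S
    return ReconstructedAdjacency(R=R, eta=eta, psi=psi, phi=phi)


def _check_weights(**weights):
    for name, w in weights.items():
        if w < 0:
            raise ValueError(f"{name} must be nonnegative, got {w}")


def _dense(A) -> np.ndarray:
    if sp.issparse(A):
        return np.asarray(A.todense(), dtype=float)
    return np.asarray(A, dtype=float)


def penalty_matrix(recon: ReconstructedAdjacency | np.ndarray, chi: float) -> PenaltyMatrix:
    """B per the indicator rule: chi on the nonzero support of R, 1 elsewhere."""
    if chi <= 1:
        raise ValueError(f"chi must be > 1, got {chi}")
    R = recon.R if isinstance(recon, ReconstructedAdjacency) else np.asarray(recon, dtype=float)
    B = np.where(np.abs(R) > ZERO_TOL, float(chi), 1.0)
    return PenaltyMatrix(B=B, chi=float(chi))


def build_reconstruction(
    G: AttributedGraph,
    community: CommunityAssignment | None,
    variant: str = "csm",
    eta: float = 1.0,
    psi: float = 1.0,
    phi: float = 1.0,
    chi: float = 10.0,
) -> tuple[ReconstructedAdjacency, PenaltyMatrix]:
    """Assemble (R, B) for a graph, its community assignment, and a variant.

    With ``community=None`` the community terms are dropped (the
    no-community-information mode used on unattributed connectomes); with
    ``G.X`` absent the attribute terms are dropped (structure-only mode).
    """
    variant = variant.lower()
    C = community.C if community is not None else None
    if variant == "am":
        W = concat_attributes_community(G.X, C)
        recon = reconstructed_adjacency_am(G.A, cosine_similarity_matrix(W), eta, psi)
    elif variant == "csm":
        X_S = None if G.X is None else cosine_similarity_matrix(G.X)
        C_S = cosine_similarity_matrix(C) if C is not None else np.zeros((G.n, G.n))
        recon = reconstructed_adjacency_csm(G.A, X_S, C_S, eta, psi, phi)
    else:
        raise ValueError(f"unknown variant {variant!r}; expected 'am' or 'csm'")
    return recon, penalty_matrix(recon, chi)
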