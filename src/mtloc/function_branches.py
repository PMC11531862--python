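"""Per-ontology function branches: projection, graph autoencoder and head.

Each GO sub-ontology (BP, CC, MF) owns an independent branch.  The shared
encoder output is projected by two stacked affine maps (no interleaved
activation — implemented literally as specified, although the composition is
itself affine), encoded by a one-layer graph convolution over the
symmetric-normalised adjacency with self-loops (LeakyReLU), and decoded by
inner products to reconstruct that adjacency; the mean squared error over
all n² entries is the branch's reconstruction loss.  Function scores come
from self-attention pooling followed by a two-layer MLP with sigmoid
outputs.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, const_matmul, leaky_relu, relu, sigmoid
from .nn import Linear, MLP, Module
from .sat_pool import SelfAttentionPool

__all__ = [
    "normalized_adjacency",
    "gae_reconstruction_loss",
    "FunctionBranch",
]


def normalized_adjacency(edge_index: np.ndarray, n: int) -> sp.csr_matrix:
    """Symmetric-normalised adjacency with self-loops, D̂^{-1/2} Ā D̂^{-1/2}.

    Ā = A + I where A is the binary contact adjacency; D̂ is the diagonal of
    Ā's row sums.  Returned sparse so it can be applied without
    materialising n×n densely.
    """
    edge_index = np.asarray(edge_index, dtype=np.int64).reshape(-1, 2)
    rows = np.concatenate([edge_index[:, 0], np.arange(n)])
    cols = np.concatenate([edge_index[:, 1], np.arange(n)])
    data = np.ones(rows.shape[0])
    a_bar = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    a_bar.data[:] = 1.0  # tolerate duplicated edge listings
    deg = np.asarray(a_bar.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    d_inv = sp.diags(inv_sqrt)
    return (d_inv @ a_bar @ d_inv).tocsr()


def dense_adjacency_with_self_loops(edge_index: np.ndarray, n: int) -> np.ndarray:
    a_bar = np.eye(n)
    for i, j in np.asarray(edge_index, dtype=np.int64).reshape(-1, 2):
        a_bar[i, j] = 1.0
    return a_bar


def gae_reconstruction_loss(h_fun: Tensor, edge_index: np.ndarray, n: int) -> Tensor:
    """MSE between sigmoid(H Hᵀ) and the self-looped adjacency Ā.

    Averaged over all n² entries, diagonal included (Ā carries self-loops).
    """
    a_bar = dense_adjacency_with_self_loops(edge_index, n)
    a_hat = sigmoid(h_fun @ h_fun.T)
    diff = a_hat - a_bar
    return (diff * diff).mean()


class FunctionBranch(Module):
    """One GO sub-ontology branch (projection → GAE → score head)."""

    def __init__(self, ontology: str, d_p: int, d_fe: int, n_terms: int,
                 pool_ratio: float, rng: np.random.Generator,
                 leaky_slope: float = 0.01, use_gae: bool = True):
        super().__init__()
        self.ontology = ontology
        self.proj1 = Linear(d_p, d_fe, rng)
        self.proj2 = Linear(d_fe, d_fe, rng)
        self.W_f = Linear(d_fe, d_fe, rng, bias=False)
        self.pool = SelfAttentionPool(d_fe, pool_ratio, rng)
        self.head = MLP(2 * d_fe, d_fe, n_terms, rng, activation=relu)
        self.leaky_slope = leaky_slope
        self.use_gae = use_gae
        self.n_terms = n_terms

    def project(self, H: Tensor) -> Tensor:
        """Two stacked affine maps, literally W²(W¹H + b¹) + b²."""
        return self.proj2(self.proj1(H))

    def gae_encode(self, h_mid: Tensor, a_norm) -> Tensor:
        """One graph-convolution layer: LeakyReLU(Â H W)."""
        return leaky_relu(const_matmul(a_norm, self.W_f(h_mid)), self.leaky_slope)

    def features(self, H: Tensor, a_norm) -> Tensor:
        """Branch node features H_fun; the GAE step is skipped when ablated."""
        h_mid = self.project(H)
        if not self.use_gae:
            return h_mid
        return self.gae_encode(h_mid, a_norm)

    def scores_from_pooled(self, pooled: Tensor) -> Tensor:
        """Term probabilities from a pooled graph vector (batch rows)."""
        out = sigmoid(self.head(pooled))
        if out.shape[-1] != self.n_terms:
            raise ValueError(
                f"{self.ontology}: head produced {out.shape[-1]} scores for "
                f"{self.n_terms} terms"
            )
        return out
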