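"""Functional cross-attention fusing the three GO branches into
localization features.

Each branch feature matrix first passes through its own two-layer nonlinear
transform.  Three independent multi-head attention groups then attend
densely over the protein's residues, with queries drawn from the BP
features, keys from MF and values from CC (the asymmetric assignment is
kept exactly as specified).  The three group outputs are averaged
node-wise, projected and passed through a residual expand-then-contract
feed-forward block, yielding the localization node features H_SL.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, relu, sigmoid, softmax
from .nn import Linear, MLP, Module
from .sat_pool import SelfAttentionPool

__all__ = ["NLinear", "CrossAttentionGroup", "FunAttention", "LocalizationHead"]


class NLinear(Module):
    """Nonlinear transform: affine → ReLU → affine, row-wise."""

    def __init__(self, d_fe: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d_fe, d_fe, rng)
        self.fc2 = Linear(d_fe, d_fe, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(x)))


class CrossAttentionGroup(Module):
    """One multi-head scaled dot-product attention group over residues."""

    def __init__(self, d_fe: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_fe % n_heads:
            raise ValueError("d_fe must be divisible by the head count")
        self.W_Q = Linear(d_fe, d_fe, rng, bias=False)
        self.W_K = Linear(d_fe, d_fe, rng, bias=False)
        self.W_V = Linear(d_fe, d_fe, rng, bias=False)
        self.n_heads = n_heads
        self.d_head = d_fe // n_heads

    def __call__(self, h_q: Tensor, h_k: Tensor, h_v: Tensor) -> Tensor:
        n = h_q.shape[0]
        if n == 0:
            raise ValueError("cross-attention requires at least one residue")

        def heads(x: Tensor) -> Tensor:  # (n, d_fe) -> (h, n, d_head)
            return x.reshape(n, self.n_heads, self.d_head).swapaxes(0, 1)

        Q, K, V = heads(self.W_Q(h_q)), heads(self.W_K(h_k)), heads(self.W_V(h_v))
        scores = (Q @ K.T) * (1.0 / np.sqrt(self.d_head))  # (h, n, n)
        attn = softmax(scores, axis=-1)
        out = attn @ V  # (h, n, d_head)
        return out.swapaxes(0, 1).reshape(n, self.n_heads * self.d_head)

    def attention_weights(self, h_q: Tensor, h_k: Tensor) -> np.ndarray:
        """Row-stochastic attention matrices (h, n, n), for inspection."""
        n = h_q.shape[0]
        Q = self.W_Q(h_q).reshape(n, self.n_heads, self.d_head).swapaxes(0, 1)
        K = self.W_K(h_k).reshape(n, self.n_heads, self.d_head).swapaxes(0, 1)
        return softmax((Q @ K.T) * (1.0 / np.sqrt(self.d_head)), axis=-1).data


class FunAttention(Module):
    """Three nLinear transforms, three attention groups, fusion + FFN.

    With ``ablate_attention`` the dense attention is dropped and the three
    transformed branch features are summed element-wise before the output
    projection; the rest of the block is unchanged.
    """

    def __init__(self, d_fe: int, d_f: int, n_heads: int,
                 rng: np.random.Generator, ablate_attention: bool = False):
        super().__init__()
        self.nlinear_bp = NLinear(d_fe, rng)
        self.nlinear_cc = NLinear(d_fe, rng)
        self.nlinear_mf = NLinear(d_fe, rng)
        self.groups = [CrossAttentionGroup(d_fe, n_heads, rng) for _ in range(3)]
        self.O_t = Linear(d_fe, d_f, rng, bias=False)
        self.W_F1 = Linear(d_f, 2 * d_f, rng, bias=False)
        self.W_F2 = Linear(2 * d_f, d_f, rng, bias=False)
        self.ablate_attention = ablate_attention

    def cross_attend(self, x_bp: Tensor, x_mf: Tensor, x_cc: Tensor):
        """Q←BP, K←MF, V←CC for each of the three groups."""
        return tuple(g(x_bp, x_mf, x_cc) for g in self.groups)

    def fuse(self, h1: Tensor, h2: Tensor, h3: Tensor) -> Tensor:
        mean = (h1 + h2 + h3) * (1.0 / 3.0)
        h_f = relu(self.O_t(mean))
        return h_f + relu(self.W_F2(relu(self.W_F1(h_f))))

    def __call__(self, h_bp: Tensor, h_cc: Tensor, h_mf: Tensor) -> Tensor:
        x_bp = self.nlinear_bp(h_bp)
        x_cc = self.nlinear_cc(h_cc)
        x_mf = self.nlinear_mf(h_mf)
        if self.ablate_attention:
            h_f = relu(self.O_t(x_bp + x_cc + x_mf))
            return h_f + relu(self.W_F2(relu(self.W_F1(h_f))))
        h1, h2, h3 = self.cross_attend(x_bp, x_mf, x_cc)
        return self.fuse(h1, h2, h3)


class LocalizationHead(Module):
    """Self-attention pooling of H_SL followed by a sigmoid MLP over classes."""

    def __init__(self, d_f: int, n_classes: int, pool_ratio: float,
                 rng: np.random.Generator):
        super().__init__()
        self.pool = SelfAttentionPool(d_f, pool_ratio, rng)
        self.head = MLP(2 * d_f, d_f, n_classes, rng, activation=relu)
        self.n_classes = n_classes

    def scores_from_pooled(self, pooled: Tensor) -> Tensor:
        out = sigmoid(self.head(pooled))
        if out.shape[-1] != self.n_classes:
            raise ValueError(
                f"localization head produced {out.shape[-1]} scores for "
                f"{self.n_classes} classes"
            )
        return out
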