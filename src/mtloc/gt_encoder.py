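"""Edge-featured graph-transformer encoder.

Each layer batch-normalises the incoming node and edge features, forms
per-head queries/keys/values/edge projections, scores every directed contact
(i → j) channel-wise as ``(Q_i ⊙ K_j)/sqrt(d_k) ⊙ E_ij``, normalises the
scores with a softmax over each node's neighbourhood (independently per head
and channel), and aggregates messages ``w_ij ⊙ V_j`` by summation.  Node and
edge streams both carry residual connections and a SiLU feed-forward block.
Attention is restricted to contact-map edges; no self-loops are added (the
residual term already preserves self-information), and a node with no
neighbours receives a zero attention message.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, segment_softmax, segment_sum, silu
from .config import ModelConfig
from .nn import BatchNorm1d, Linear, Module

__all__ = ["GTState", "InputProjection", "GTLayer", "GTEncoder"]


class NumericError(FloatingPointError):
    """NaN/Inf appeared inside the encoder."""


class GTState:
    """Node features H (n×d_p) and edge features E (|E|×d_p) at layer l."""

    __slots__ = ("H", "E", "layer")

    def __init__(self, H: Tensor, E: Tensor, layer: int = 0):
        self.H = H
        self.E = E
        self.layer = layer


class InputProjection(Module):
    """Two linear layers lifting raw node/edge features to width d_p."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.node = Linear(config.d_h, config.d_p, rng)
        self.edge = Linear(config.d_e, config.d_p, rng)
        self.d_h, self.d_e = config.d_h, config.d_e

    def __call__(self, node_feats: Tensor, edge_feats: Tensor) -> GTState:
        if node_feats.shape[1] != self.d_h or edge_feats.shape[-1] != self.d_e:
            raise ValueError(
                f"input dims ({node_feats.shape[1]}, {edge_feats.shape[-1]}) do not "
                f"match configured (d_h={self.d_h}, d_e={self.d_e})"
            )
        return GTState(self.node(node_feats), self.edge(edge_feats), layer=0)


class GTLayer(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d_p = config.d_p
        self.h_d, self.d_k = config.h_d, config.d_k
        # per-head projections packed into single d_p×d_p maps
        self.W_Q = Linear(d_p, d_p, rng, bias=False)
        self.W_K = Linear(d_p, d_p, rng, bias=False)
        self.W_V = Linear(d_p, d_p, rng, bias=False)
        self.W_E = Linear(d_p, d_p, rng, bias=False)
        self.W_h0 = Linear(d_p, d_p, rng, bias=False)
        self.W_e0 = Linear(d_p, d_p, rng, bias=False)
        self.W_h1 = Linear(d_p, 2 * d_p, rng, bias=False)
        self.W_h2 = Linear(2 * d_p, d_p, rng, bias=False)
        self.W_e1 = Linear(d_p, 2 * d_p, rng, bias=False)
        self.W_e2 = Linear(2 * d_p, d_p, rng, bias=False)
        self.norm_h = BatchNorm1d(d_p)
        self.norm_e = BatchNorm1d(d_p)
        self.norm_h_ffn = BatchNorm1d(d_p)
        self.norm_e_ffn = BatchNorm1d(d_p)

    def __call__(self, state: GTState, edge_index: np.ndarray) -> GTState:
        H, E = state.H, state.E
        n = H.shape[0]
        if edge_index.size:
            src, dst = edge_index[:, 0], edge_index[:, 1]
            Hn = self.norm_h(H)
            En = self.norm_e(E)
            Q = self.W_Q(Hn)
            K = self.W_K(Hn)
            V = self.W_V(Hn)
            Ep = self.W_E(En)
            # per directed edge (i -> j): channel-wise score, then softmax
            # over j in N(i), independently per head and channel
            scores = (Q[src] * K[dst]) * (1.0 / np.sqrt(self.d_k)) * Ep
            w = segment_softmax(scores, src, n)
            agg = segment_sum(w * V[dst], src, n)
            H_bar = H + self.W_h0(agg)
            E_bar = E + self.W_e0(w)
        else:  # no edges: zero attention message on every node
            H_bar = H
            E_bar = E
        H_next = H_bar + self.W_h2(silu(self.W_h1(self.norm_h_ffn(H_bar))))
        if E_bar.shape[0]:
            E_next = E_bar + self.W_e2(silu(self.W_e1(self.norm_e_ffn(E_bar))))
        else:
            E_next = E_bar
        _check_finite(H_next, E_next, state.layer)
        return GTState(H_next, E_next, state.layer + 1)


def _check_finite(H: Tensor, E: Tensor, layer: int) -> None:
    if not np.isfinite(H.data).all() or (E.data.size and not np.isfinite(E.data).all()):
        raise NumericError(f"non-finite values after graph-transformer layer {layer}")


class GTEncoder(Module):
    """Input projection followed by L graph-transformer layers."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        if config.n_gt_layers < 1:
            raise ValueError("encoder needs at least one layer")
        self.project = InputProjection(config, rng)
        self.layers = [GTLayer(config, rng) for _ in range(config.n_gt_layers)]
        self.skip_layers = config.no_gt

    def __call__(self, node_feats: Tensor, edge_feats: Tensor,
                 edge_index: np.ndarray) -> GTState:
        state = self.project(node_feats, edge_feats)
        if self.skip_layers:
            return state
        for layer in self.layers:
            state = layer(state, edge_index)
        return state
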