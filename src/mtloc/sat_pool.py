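"""Self-attention graph pooling (SAGPool-style top-k node masking).

A single graph-convolution layer (symmetric-normalised adjacency with
self-loops) projects node features to a scalar score per residue.  The
top ``ceil(r * n)`` nodes by score are retained (ties broken toward the
lower residue index), their features are gated by ``tanh(score)``, and the
readout concatenates the mean and max of the gated features, giving a
fixed-length vector of size ``2 * d_in``.  The raw scores double as
per-residue importance values for interpretability.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, const_matmul, tanh
from .nn import Linear, Module

__all__ = ["SelfAttentionPool", "residue_importance_from_scores"]


class SelfAttentionPool(Module):
    def __init__(self, d_in: int, ratio: float, rng: np.random.Generator):
        super().__init__()
        if not (0 < ratio <= 1):
            raise ValueError("pooling ratio must lie in (0, 1]")
        self.score_proj = Linear(d_in, 1, rng, bias=False)
        self.ratio = ratio
        self.d_in = d_in

    def node_scores(self, H: Tensor, a_norm) -> Tensor:
        """Raw (pre-activation) attention score per node: Â H w."""
        return const_matmul(a_norm, self.score_proj(H)).reshape(-1)

    def __call__(self, H: Tensor, a_norm) -> tuple[Tensor, Tensor]:
        """Pool one graph; returns (readout vector of length 2*d_in, scores)."""
        n = H.shape[0]
        scores = self.node_scores(H, a_norm)
        k = int(np.ceil(self.ratio * n))
        # stable sort on -score keeps lower residue index first among ties
        keep = np.argsort(-scores.data, kind="stable")[:k]
        keep.sort()  # readout is order-invariant; sorted indices aid debugging
        gate = tanh(scores[keep]).reshape(-1, 1)
        masked = H[keep] * gate
        readout = concat([masked.mean(axis=0), masked.max(axis=0)])
        return readout, scores


def residue_importance_from_scores(scores: np.ndarray) -> np.ndarray:
    """Min–max normalise raw pooling scores to [0, 1] per protein.

    A constant score vector maps to all 0.5 by convention.
    """
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi - lo < 1e-12:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)
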