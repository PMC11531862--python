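"""Task losses and the weighted collaborative total.

The total objective is

    L = α (L_bp_bce + L_cc_bce + L_mf_bce)
      + β (L_bp_mse + L_cc_mse + L_mf_mse)
      + ω  L_sl

where the BCE terms supervise the three GO branches and the localization
head, and the MSE terms are the graph-autoencoder reconstruction losses.
α, β, ω set the share of each task; the ablation flags act by zeroing
weights (collaborative training off → α = β = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, log
from .io_formats import ConfigError

EPS = 1e-7

__all__ = ["LossBundle", "bce_multilabel", "total_loss", "EPS"]


@dataclass
class LossBundle:
    """All loss components of one forward pass, plus the weighted total."""

    bp_bce: Tensor
    cc_bce: Tensor
    mf_bce: Tensor
    bp_mse: Tensor
    cc_mse: Tensor
    mf_mse: Tensor
    sl: Tensor
    total: Tensor
    alpha: float
    beta: float
    omega: float

    def as_floats(self) -> dict[str, float]:
        return {
            name: float(getattr(self, name).data)
            for name in ("bp_bce", "cc_bce", "mf_bce", "bp_mse", "cc_mse",
                         "mf_mse", "sl", "total")
        }


def bce_multilabel(pred: Tensor, true: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over all N×M prediction entries.

    Predictions are clamped to [EPS, 1−EPS] before the logarithms.
    """
    pred = as_tensor(pred)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError(f"prediction shape {pred.shape} != label shape {true.shape}")
    clamped = _clamp01(pred)
    ll = true * log(clamped) + (1.0 - true) * log(1.0 - clamped)
    return -ll.mean()


def _clamp01(pred: Tensor) -> Tensor:
    """Clamp probabilities into [EPS, 1-EPS]; gradient passes through the
    interior and is zeroed on clamped entries."""
    lo = pred.data < EPS
    hi = pred.data > 1.0 - EPS
    data = np.clip(pred.data, EPS, 1.0 - EPS)
    mask = ~(lo | hi)

    def backward(g):
        pred._accum(g * mask)

    return Tensor._from_op(data, (pred,), backward)


def total_loss(bp_bce, cc_bce, mf_bce, bp_mse, cc_mse, mf_mse, sl,
               alpha: float = 1.0, beta: float = 1.0, omega: float = 1.0) -> LossBundle:
    """Combine the seven components into the collaborative objective."""
    if min(alpha, beta, omega) < 0:
        raise ConfigError("loss weights must be nonnegative")
    parts = [as_tensor(x) for x in (bp_bce, cc_bce, mf_bce, bp_mse, cc_mse,
                                    mf_mse, sl)]
    bp_bce, cc_bce, mf_bce, bp_mse, cc_mse, mf_mse, sl = parts
    total = (alpha * (bp_bce + cc_bce + mf_bce)
             + beta * (bp_mse + cc_mse + mf_mse)
             + omega * sl)
    return LossBundle(bp_bce=bp_bce, cc_bce=cc_bce, mf_bce=mf_bce,
                      bp_mse=bp_mse, cc_mse=cc_mse, mf_mse=mf_mse,
                      sl=sl, total=total, alpha=alpha, beta=beta, omega=omega)
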