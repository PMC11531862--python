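"""Model configuration: every dimension, head count, loss weight and flag."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .io_formats import ConfigError

__all__ = ["ModelConfig"]


@dataclass
class ModelConfig:
    """Hyperparameters of the multi-task localization model.

    Dimensions
    ----------
    d_h, d_e : input node / edge feature widths.
    d_p      : graph-transformer width; must equal ``h_d * d_k``.
    h_d      : attention heads in the graph transformer.
    n_gt_layers : number of graph-transformer layers.
    d_fe     : branch (graph-autoencoder) feature width; equals ``h_ki * d_ki``.
    d_f      : fused localization feature width.
    h_ki     : heads per functional cross-attention group.
    pool_ratio : fraction of nodes kept by self-attention pooling.

    Tasks
    -----
    m_bp, m_cc, m_mf : GO vocabulary sizes; c_sl : localization classes.
    alpha, beta, omega : loss weights for the function BCE group, the
    reconstruction MSE group and the localization BCE.

    Ablations
    ---------
    no_gt   : skip the graph transformer (input projection only).
    no_funA : replace cross-attention fusion by a sum of the branch features.
    no_feaE : bypass the graph autoencoders (beta forced to 0).
    no_colT : drop the collaborative objective (alpha = beta = 0); the
              forward computation is unchanged.
    """

    d_h: int = 32
    d_e: int = 42
    d_p: int = 128
    h_d: int = 4
    n_gt_layers: int = 2
    d_fe: int = 64
    d_f: int = 64
    h_ki: int = 4
    pool_ratio: float = 0.5
    m_bp: int = 8
    m_cc: int = 5
    m_mf: int = 5
    c_sl: int = 10
    alpha: float = 1.0
    beta: float = 1.0
    omega: float = 1.0
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0
    contact_threshold: float = 4.5
    leaky_slope: float = 0.01
    no_gt: bool = False
    no_funA: bool = False
    no_feaE: bool = False
    no_colT: bool = False

    def __post_init__(self):
        if self.d_p % self.h_d:
            raise ConfigError(f"d_p={self.d_p} not divisible by h_d={self.h_d}")
        if self.d_fe % self.h_ki:
            raise ConfigError(f"d_fe={self.d_fe} not divisible by h_ki={self.h_ki}")
        if not (0 < self.pool_ratio <= 1):
            raise ConfigError("pool_ratio must lie in (0, 1]")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.contact_threshold <= 0:
            raise ConfigError("contact_threshold must be positive")
        if min(self.alpha, self.beta, self.omega) < 0:
            raise ConfigError("loss weights must be nonnegative")

    @property
    def d_k(self) -> int:
        return self.d_p // self.h_d

    @property
    def d_ki(self) -> int:
        return self.d_fe // self.h_ki

    def effective_weights(self) -> tuple[float, float, float]:
        """(alpha, beta, omega) after applying the ablation flags."""
        alpha, beta, omega = self.alpha, self.beta, self.omega
        if self.no_colT:
            alpha, beta = 0.0, 0.0
        if self.no_feaE:
            beta = 0.0
        return alpha, beta, omega

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
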