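"""The assembled multi-task model: graph-transformer encoder, three GO
branches with graph autoencoders, functional cross-attention fusion, and
the multi-label localization head.

A batch of proteins is processed as one block-diagonal graph: node and edge
features are concatenated (which also makes batch normalisation operate over
the whole batch), while the dense cross-attention, pooling and adjacency
reconstruction are applied per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, as_tensor, concat, stack_rows
from .config import ModelConfig
from .contact_graph import ResidueGraph
from .fun_attention import FunAttention, LocalizationHead
from .function_branches import (FunctionBranch, gae_reconstruction_loss,
                                normalized_adjacency)
from .gt_encoder import GTEncoder
from .nn import Module
from .sat_pool import residue_importance_from_scores

__all__ = ["PredictionBundle", "MultiTaskModel", "BatchedGraphs"]

ONTOLOGIES = ("bp", "cc", "mf")


@dataclass
class PredictionBundle:
    """Per-protein score vectors for the four tasks plus residue importances."""

    protein_id: str
    bp: np.ndarray
    cc: np.ndarray
    mf: np.ndarray
    sl: np.ndarray
    residue_importance: np.ndarray = field(default_factory=lambda: np.zeros(0))


class BatchedGraphs:
    """Block-diagonal concatenation of a list of residue graphs."""

    def __init__(self, graphs: list[ResidueGraph]):
        if not graphs:
            raise ValueError("empty batch")
        self.graphs = graphs
        self.sizes = [g.n_nodes for g in graphs]
        offsets = np.cumsum([0] + self.sizes)
        self.offsets = offsets
        self.n_total = int(offsets[-1])
        self.node_feats = np.concatenate([g.node_feats for g in graphs])
        parts = [g.edge_index + off for g, off in zip(graphs, offsets)]
        self.edge_index = (np.concatenate(parts) if any(p.size for p in parts)
                           else np.zeros((0, 2), dtype=np.int64))
        self.edge_feats = np.concatenate([g.edge_feats for g in graphs])
        self.a_norms = [_cached_a_norm(g) for g in graphs]
        self.a_norm_block = sp.block_diag(self.a_norms, format="csr")

    def slices(self):
        for i, g in enumerate(self.graphs):
            yield g, slice(int(self.offsets[i]), int(self.offsets[i + 1]))


def _cached_a_norm(graph: ResidueGraph) -> sp.csr_matrix:
    cached = getattr(graph, "_a_norm", None)
    if cached is None or cached.shape[0] != graph.n_nodes:
        cached = normalized_adjacency(graph.edge_index, graph.n_nodes)
        graph._a_norm = cached
    return cached


class MultiTaskModel(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator | int | None = None):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(config.seed if rng is None else rng)
        self.config = config
        self.encoder = GTEncoder(config, rng)
        self.branches = {
            "bp": FunctionBranch("bp", config.d_p, config.d_fe, config.m_bp,
                                 config.pool_ratio, rng, config.leaky_slope,
                                 use_gae=not config.no_feaE),
            "cc": FunctionBranch("cc", config.d_p, config.d_fe, config.m_cc,
                                 config.pool_ratio, rng, config.leaky_slope,
                                 use_gae=not config.no_feaE),
            "mf": FunctionBranch("mf", config.d_p, config.d_fe, config.m_mf,
                                 config.pool_ratio, rng, config.leaky_slope,
                                 use_gae=not config.no_feaE),
        }
        self.fun_attention = FunAttention(config.d_fe, config.d_f, config.h_ki,
                                          rng, ablate_attention=config.no_funA)
        self.sl_head = LocalizationHead(config.d_f, config.c_sl,
                                        config.pool_ratio, rng)

    # -- forward -----------------------------------------------------------
    def forward(self, graphs: list[ResidueGraph] | BatchedGraphs):
        """Run the full pipeline on a batch.

        Returns a dict with score tensors ``bp``/``cc``/``mf``/``sl`` of
        shape (B, M_task), reconstruction-loss tensors ``bp_mse``/… (batch
        means), and per-protein numpy importance vectors under
        ``importance``.
        """
        batch = graphs if isinstance(graphs, BatchedGraphs) else BatchedGraphs(graphs)
        try:
            return self._forward_batch(batch)
        except Exception as exc:
            ids = [g.protein_id for g in batch.graphs]
            raise type(exc)(f"{exc} [batch proteins: {ids}]") from exc

    __call__ = forward

    def _forward_batch(self, batch: BatchedGraphs):
        state = self.encoder(Tensor(batch.node_feats), Tensor(batch.edge_feats),
                             batch.edge_index)
        H = state.H

        branch_feats: dict[str, Tensor] = {}
        recon: dict[str, Tensor] = {}
        scores: dict[str, Tensor] = {}
        for tag in ONTOLOGIES:
            branch = self.branches[tag]
            h_fun = branch.features(H, batch.a_norm_block)
            branch_feats[tag] = h_fun
            if branch.use_gae:
                per_graph = [
                    gae_reconstruction_loss(h_fun[sl_], g.edge_index, g.n_nodes)
                    for g, sl_ in batch.slices()
                ]
                recon[f"{tag}_mse"] = _mean_scalars(per_graph)
            else:
                recon[f"{tag}_mse"] = as_tensor(0.0)
            pooled = stack_rows([
                branch.pool(h_fun[sl_], a)[0]
                for (g, sl_), a in zip(batch.slices(), batch.a_norms)
            ])
            scores[tag] = branch.scores_from_pooled(pooled)

        # localization pathway: per-protein dense cross-attention
        sl_parts = [
            self.fun_attention(branch_feats["bp"][sl_], branch_feats["cc"][sl_],
                               branch_feats["mf"][sl_])
            for g, sl_ in batch.slices()
        ]
        h_sl = concat(sl_parts, axis=0)

        pooled_sl = []
        importance = []
        for (g, sl_), a in zip(batch.slices(), batch.a_norms):
            vec, node_scores = self.sl_head.pool(h_sl[sl_], a)
            pooled_sl.append(vec)
            importance.append(residue_importance_from_scores(node_scores.data))
        scores["sl"] = self.sl_head.scores_from_pooled(stack_rows(pooled_sl))

        return {**scores, **recon, "importance": importance,
                "protein_ids": [g.protein_id for g in batch.graphs]}

    def predict(self, graphs: list[ResidueGraph]) -> list[PredictionBundle]:
        """Deterministic eval-mode prediction for a list of proteins."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(graphs)
        finally:
            if was_training:
                self.train()
        bundles = []
        for i, g in enumerate(graphs):
            bundles.append(PredictionBundle(
                protein_id=g.protein_id,
                bp=out["bp"].data[i], cc=out["cc"].data[i],
                mf=out["mf"].data[i], sl=out["sl"].data[i],
                residue_importance=out["importance"][i]))
        return bundles


def _mean_scalars(scalars: list[Tensor]) -> Tensor:
    total = scalars[0]
    for s in scalars[1:]:
        total = total + s
    return total * (1.0 / len(scalars))
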