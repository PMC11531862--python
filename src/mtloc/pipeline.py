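"""Glue between raw inputs (files or synthetic corpora) and training samples."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import ModelConfig
from .contact_graph import (EdgeFeatureConfig, ResidueGraph, build_contact_map,
                            compute_edge_features)
from .io_formats import (LabelVocabulary, build_vocabulary, labels_to_matrix,
                         read_coords, read_fasta, read_label_table)
from .synthetic_data import SimConfig, SyntheticProtein
from .training import GraphSample

__all__ = ["graph_from_arrays", "samples_from_corpus", "load_dataset_dir",
           "model_config_for_sim"]


def graph_from_arrays(node_feats: np.ndarray, coords: np.ndarray,
                      threshold: float = 4.5,
                      edge_config: EdgeFeatureConfig | None = None,
                      protein_id: str = "?") -> ResidueGraph:
    edge_index = build_contact_map(coords, threshold)
    edge_feats = compute_edge_features(coords, edge_index, edge_config)
    return ResidueGraph(node_feats=node_feats, edge_index=edge_index,
                        edge_feats=edge_feats, coords=coords,
                        protein_id=protein_id)


def samples_from_corpus(proteins: list[SyntheticProtein],
                        threshold: float = 4.5,
                        edge_config: EdgeFeatureConfig | None = None) -> list[GraphSample]:
    """Featurise an in-memory synthetic corpus into training samples."""
    samples = []
    for p in proteins:
        graph = graph_from_arrays(p.embedding, p.record.coords, threshold,
                                  edge_config, protein_id=p.record.id)
        samples.append(GraphSample(graph=graph, go_bp=p.record.go_bp,
                                   go_cc=p.record.go_cc, go_mf=p.record.go_mf,
                                   sl=p.record.sl))
    return samples


def model_config_for_sim(sim: SimConfig, **overrides) -> ModelConfig:
    """A model config whose input and task dimensions match a simulation."""
    params = dict(
        d_h=sim.embedding_dim,
        m_bp=len(sim.terms("bp")),
        m_cc=len(sim.terms("cc")),
        m_mf=len(sim.terms("mf")),
        c_sl=len(sim.sl_rules),
        contact_threshold=sim.contact_threshold,
    )
    params.update(overrides)
    return ModelConfig(**params)


def load_dataset_dir(path, min_frequency: int = 1,
                     threshold: float = 4.5,
                     edge_config: EdgeFeatureConfig | None = None):
    """Read a dataset directory (the synthetic layout) into samples.

    Returns ``(samples, vocabs)`` where vocabs maps task tag to its
    :class:`LabelVocabulary` (built with `min_frequency` for the GO tables;
    localization classes are kept unfiltered).
    """
    path = Path(path)
    seq = read_fasta(path / "sequences.fasta")
    ids = [pid for pid, _ in seq]

    vocabs: dict[str, LabelVocabulary] = {}
    matrices: dict[str, np.ndarray] = {}
    for tag in ("bp", "cc", "mf"):
        table = read_label_table(path / f"labels_{tag}.tsv")
        vocabs[tag] = build_vocabulary(table, min_frequency, ontology=tag.upper())
        matrices[tag] = labels_to_matrix(table, ids, vocabs[tag])
    sl_table = read_label_table(path / "labels_sl.tsv")
    vocabs["sl"] = build_vocabulary(sl_table, 1, ontology="SL")
    matrices["sl"] = labels_to_matrix(sl_table, ids, vocabs["sl"])

    samples = []
    for row, (pid, sequence) in enumerate(seq):
        coords = read_coords(path / "coords" / f"{pid}.xyz")
        emb = np.loadtxt(path / "embeddings" / f"{pid}.tsv", ndmin=2)
        graph = graph_from_arrays(emb, coords, threshold, edge_config,
                                  protein_id=pid)
        samples.append(GraphSample(graph=graph,
                                   go_bp=matrices["bp"][row],
                                   go_cc=matrices["cc"][row],
                                   go_mf=matrices["mf"][row],
                                   sl=matrices["sl"][row]))
    return samples, vocabs
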