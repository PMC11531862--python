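"""Residue contact graphs and their node/edge featurisation.

A protein is represented as a graph over its residues: nodes carry
per-residue embeddings from an :class:`EmbeddingProvider`, and an edge joins
every pair of residues whose Cα atoms lie within a distance threshold
(4.5 Å by default).  Edge features are purely geometric and translation
invariant:

[a] the Cα–Cα distance (1 dim);
[b] sine/cosine encodings of each component of the displacement vector at
    ``n_frequencies`` geometric frequencies (3·2·F dims);
[c] displacements from the source residue to its five spatially nearest
    residues, flattened and zero-padded for short chains (15 dims);
[d] the summed distance from each endpoint to its five nearest residues
    (2 dims).

With the default F=4 this gives d_e = 1 + 24 + 15 + 2 = 42.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import FormatError, ConfigError

CONTACT_THRESHOLD = 4.5  # Å
N_SPATIAL_NEIGHBOURS = 5

__all__ = [
    "ResidueGraph",
    "EdgeFeatureConfig",
    "EmbeddingProvider",
    "SyntheticEmbeddingProvider",
    "TableEmbeddingProvider",
    "build_contact_map",
    "compute_edge_features",
    "init_node_features",
    "build_graph",
    "save_graph",
    "load_graph",
]


@dataclass
class ResidueGraph:
    """One protein as a featurised contact graph.

    ``edge_index`` has shape (|E|, 2) and stores both directions of every
    contact; ``edge_feats`` row k belongs to ``edge_index[k]``.
    """

    node_feats: np.ndarray
    edge_index: np.ndarray
    edge_feats: np.ndarray
    coords: np.ndarray
    protein_id: str = "?"

    def __post_init__(self):
        self.node_feats = np.asarray(self.node_feats, dtype=float)
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        self.edge_feats = np.asarray(self.edge_feats, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if self.node_feats.shape[0] != n:
            raise FormatError(
                f"graph {self.protein_id}: {self.node_feats.shape[0]} node-feature "
                f"rows for {n} residues"
            )
        if self.edge_index.size:
            if (self.edge_index[:, 0] == self.edge_index[:, 1]).any():
                raise FormatError(f"graph {self.protein_id}: self-edges present")
            fwd = {tuple(e) for e in self.edge_index}
            if any((j, i) not in fwd for i, j in fwd):
                raise FormatError(f"graph {self.protein_id}: edge set not symmetric")
        if self.edge_feats.shape[0] != self.edge_index.shape[0]:
            raise FormatError(
                f"graph {self.protein_id}: edge feature rows != number of edges"
            )

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]


@dataclass(frozen=True)
class EdgeFeatureConfig:
    n_frequencies: int = 4
    n_neighbours: int = N_SPATIAL_NEIGHBOURS
    base_frequency: float = 1.0  # rad/Å; halved at each successive frequency

    @property
    def dim(self) -> int:
        return 1 + 3 * 2 * self.n_frequencies + 3 * self.n_neighbours + 2


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Pluggable source of per-residue embeddings.

    Implementations return an L×dim (or, with flank rows, (L+f)×dim) matrix
    for a length-L sequence, deterministically for a fixed sequence and
    seed.  ``flank_rows = (before, after)`` declares special-token rows that
    :func:`init_node_features` strips.
    """

    dim: int
    flank_rows: tuple[int, int]

    def embed(self, sequence: str) -> np.ndarray: ...


class SyntheticEmbeddingProvider:
    """Deterministic pseudo-random embeddings keyed on (seed, sequence).

    Stands in for a protein language model during testing: rows are i.i.d.
    standard normal draws from a generator seeded by a hash of the sequence,
    so the same sequence always maps to the same matrix.
    """

    flank_rows = (0, 0)

    def __init__(self, dim: int = 32, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def embed(self, sequence: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self.seed}:{sequence}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little") % (2**63))
        return rng.standard_normal((len(sequence), self.dim))


class TableEmbeddingProvider:
    """Embeddings precomputed per protein and stored as whitespace tables."""

    flank_rows = (0, 0)

    def __init__(self, directory, dim: int, sequence_to_id):
        self.directory = Path(directory)
        self.dim = dim
        self._seq_to_id = dict(sequence_to_id)

    def embed(self, sequence: str) -> np.ndarray:
        pid = self._seq_to_id.get(sequence)
        if pid is None:
            raise KeyError("sequence not present in embedding table index")
        mat = np.loadtxt(self.directory / f"{pid}.tsv", ndmin=2)
        if mat.shape[1] != self.dim:
            raise FormatError(f"{pid}: embedding dim {mat.shape[1]} != {self.dim}")
        return mat


def build_contact_map(coords: np.ndarray, threshold: float = CONTACT_THRESHOLD) -> np.ndarray:
    """All ordered residue pairs (i, j), i≠j, with ‖Cα_i − Cα_j‖ ≤ threshold.

    Uses a k-d tree for the pair query; the result is identical to
    brute-force all-pairs filtering (the comparison is inclusive).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if not np.isfinite(coords).all():
        raise FormatError("non-finite coordinates")
    if threshold <= 0:
        raise ConfigError("contact threshold must be positive")
    n = coords.shape[0]
    if n < 2:
        return np.zeros((0, 2), dtype=np.int64)
    pairs = cKDTree(coords).query_pairs(r=threshold, output_type="ndarray")
    if pairs.size == 0:
        return np.zeros((0, 2), dtype=np.int64)
    both = np.vstack([pairs, pairs[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    return both[order].astype(np.int64)


def _nearest_neighbours(coords: np.ndarray, k: int):
    """Per-residue displacements to the k spatially nearest other residues.

    Ties are broken by residue index; when fewer than k other residues
    exist the trailing slots are zero-filled (and excluded from the distance
    sum).  Returns (disp: n×k×3, dist_sum: n).
    """
    n = coords.shape[0]
    disp = np.zeros((n, k, 3))
    dist_sum = np.zeros(n)
    if n < 2:
        return disp, dist_sum
    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    # stable argsort on distance => index order breaks ties; distances are
    # quantised to 1e-6 A first so the ordering (and hence the feature) is
    # robust to sub-micro-Angstrom rounding, e.g. under rigid translations
    quantised = np.round(dist * 1e6)
    order = np.argsort(quantised, axis=1, kind="stable")[:, : min(k, n - 1)]
    for i in range(n):
        m = order.shape[1]
        disp[i, :m] = diff[i, order[i]]
        dist_sum[i] = dist[i, order[i]].sum()
    return disp, dist_sum


def compute_edge_features(coords: np.ndarray, edge_index: np.ndarray,
                          config: EdgeFeatureConfig | None = None) -> np.ndarray:
    """Geometric edge features (see module docstring) as an |E|×d_e matrix."""
    config = config or EdgeFeatureConfig()
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    edge_index = np.asarray(edge_index, dtype=np.int64).reshape(-1, 2)
    if edge_index.size and edge_index.max() >= coords.shape[0]:
        raise FormatError("edge_index refers to a residue outside the chain")
    n_edges = edge_index.shape[0]
    if n_edges == 0:
        return np.zeros((0, config.dim))
    src, dst = edge_index[:, 0], edge_index[:, 1]
    delta = coords[dst] - coords[src]
    d_ij = np.linalg.norm(delta, axis=1, keepdims=True)

    freqs = config.base_frequency * (0.5 ** np.arange(config.n_frequencies))
    angles = delta[:, :, None] * freqs[None, None, :]  # |E| × 3 × F
    trig = np.concatenate([np.sin(angles), np.cos(angles)], axis=2)
    trig = trig.reshape(n_edges, -1)

    disp, dist_sum = _nearest_neighbours(coords, config.n_neighbours)
    knn_disp = disp[src].reshape(n_edges, -1)
    sums = np.stack([dist_sum[src], dist_sum[dst]], axis=1)

    feats = np.concatenate([d_ij, trig, knn_disp, sums], axis=1)
    if feats.shape[1] != config.dim:
        raise ConfigError(
            f"edge feature dim {feats.shape[1]} != configured {config.dim}"
        )
    return feats


def init_node_features(provider: EmbeddingProvider, sequence: str) -> np.ndarray:
    """Fetch per-residue embeddings and truncate them to the sequence length.

    Declared flank rows (special tokens) are stripped first; a provider
    returning fewer rows than residues is an error — rows are never padded.
    """
    mat = np.asarray(provider.embed(sequence), dtype=float)
    before, after = getattr(provider, "flank_rows", (0, 0))
    if before or after:
        mat = mat[before : mat.shape[0] - after or None]
    n = len(sequence)
    if mat.shape[0] < n:
        raise FormatError(
            f"embedding provider returned {mat.shape[0]} rows for a "
            f"{n}-residue sequence"
        )
    return mat[:n]


def build_graph(sequence: str, coords: np.ndarray, provider: EmbeddingProvider,
                threshold: float = CONTACT_THRESHOLD,
                edge_config: EdgeFeatureConfig | None = None,
                protein_id: str = "?") -> ResidueGraph:
    """Assemble a :class:`ResidueGraph` from sequence + coordinates."""
    edge_index = build_contact_map(coords, threshold)
    edge_feats = compute_edge_features(coords, edge_index, edge_config)
    node_feats = init_node_features(provider, sequence)
    return ResidueGraph(node_feats=node_feats, edge_index=edge_index,
                        edge_feats=edge_feats, coords=coords,
                        protein_id=protein_id)


_CACHE_VERSION = 1


def save_graph(graph: ResidueGraph, path) -> None:
    """Serialise one graph to a self-describing ``.npz`` cache file."""
    np.savez(path, version=np.int64(_CACHE_VERSION),
             protein_id=np.array(graph.protein_id),
             node_feats=graph.node_feats, edge_index=graph.edge_index,
             edge_feats=graph.edge_feats, coords=graph.coords)


def load_graph(path) -> ResidueGraph:
    with np.load(path, allow_pickle=False) as data:
        if int(data["version"]) != _CACHE_VERSION:
            raise FormatError(f"{path}: unsupported graph cache version")
        return ResidueGraph(node_feats=data["node_feats"],
                            edge_index=data["edge_index"],
                            edge_feats=data["edge_feats"],
                            coords=data["coords"],
                            protein_id=str(data["protein_id"]))
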