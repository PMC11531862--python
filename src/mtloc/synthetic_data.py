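"""Synthetic desk-scale datasets with planted function→localization structure.

The generator emulates the statistical assumptions the model exploits:

* **Backbones** are self-avoiding random walks with a fixed 3.8 Å step
  (the consecutive Cα–Cα distance in real chains), so contact graphs are
  connected at the 4.5 Å threshold and occasionally form long-range loops.
* **Embeddings** are i.i.d. standard-normal per residue, standing in for a
  protein language model.  For each GO term present in a protein, a random
  contiguous window of residues has its embedding shifted along a fixed
  term-specific direction — a "motif" carrying the functional signal.
* **GO labels** equal motif presence, drawn per term with a configured
  prevalence.
* **Localization labels** are boolean formulas over the GO labels (each an
  OR of AND-clauses), independently flipped with probability ``label_noise``
  — localization is driven by function, the premise the collaborative
  objective is designed to exploit.

What the generator does *not* emulate: real GO co-occurrence statistics,
language-model embedding geometry, or secondary-structure regularity.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import ProteinRecord, write_fasta

__all__ = ["MotifSpec", "SLRule", "SimConfig", "SyntheticProtein",
           "generate_backbone", "generate_protein", "generate_corpus",
           "generate_dataset", "default_motif_catalogue", "default_sl_rules"]

BOND_LENGTH = 3.8  # Å, consecutive Cα spacing


@dataclass(frozen=True)
class MotifSpec:
    """One GO term: its ontology, motif window length, embedding shift
    magnitude and population prevalence."""

    term: str
    ontology: str  # "bp" | "cc" | "mf"
    length: int = 6
    shift: float = 2.0
    prevalence: float = 0.3


@dataclass(frozen=True)
class SLRule:
    """One localization class as an OR of AND-clauses over GO terms."""

    name: str
    clauses: tuple[tuple[str, ...], ...]

    def holds(self, present: set[str]) -> bool:
        return any(all(t in present for t in clause) for clause in self.clauses)


def default_motif_catalogue() -> tuple[MotifSpec, ...]:
    """8 BP, 5 CC and 5 MF terms with moderate-length, strong motifs."""
    specs = []
    for i in range(8):
        specs.append(MotifSpec(f"bp{i:02d}", "bp", length=6 + i % 3))
    for i in range(5):
        specs.append(MotifSpec(f"cc{i:02d}", "cc", length=6 + i % 3))
    for i in range(5):
        specs.append(MotifSpec(f"mf{i:02d}", "mf", length=6 + i % 3))
    return tuple(specs)


def default_sl_rules() -> tuple[SLRule, ...]:
    """Four localization classes as small OR/AND formulas over GO terms."""
    return (
        SLRule("sl_nucleus", (("bp00",), ("bp02",))),
        SLRule("sl_membrane", (("cc00",), ("mf00",))),
        SLRule("sl_cytoplasm", (("bp03",), ("cc01", "mf01"))),
        SLRule("sl_secreted", (("mf02",), ("bp04",))),
    )


@dataclass
class SimConfig:
    n_proteins: int = 300
    length_range: tuple[int, int] = (30, 60)
    embedding_dim: int = 32
    bond_length: float = BOND_LENGTH
    excluded_radius: float = 3.0
    motifs: tuple[MotifSpec, ...] = field(default_factory=default_motif_catalogue)
    sl_rules: tuple[SLRule, ...] = field(default_factory=default_sl_rules)
    label_noise: float = 0.05
    seed: int = 0
    contact_threshold: float = 4.5

    def __post_init__(self):
        if self.bond_length >= self.contact_threshold:
            raise ValueError("bond length must stay below the contact threshold "
                             "so chains are connected")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        for m in self.motifs:
            if not (0 < m.prevalence < 1):
                raise ValueError(f"{m.term}: prevalence must lie in (0, 1)")

    def terms(self, ontology: str) -> list[str]:
        return sorted(m.term for m in self.motifs if m.ontology == ontology)

    def sl_classes(self) -> list[str]:
        return [r.name for r in self.sl_rules]


@dataclass
class SyntheticProtein:
    record: ProteinRecord
    embedding: np.ndarray
    motif_windows: dict[str, tuple[int, int]]  # term -> [start, end)
    go_terms: set[str]


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def generate_backbone(length: int, config: SimConfig | None = None,
                      seed: int = 0) -> np.ndarray:
    """Self-avoiding random walk with fixed step length.

    Steps are uniform on the sphere; a proposal closer than the excluded-
    volume radius to any earlier residue is rejected (up to 100 retries per
    step, then the chain restarts; 50 failed chains raise).
    """
    config = config or SimConfig()
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(50):
        coords = _try_chain(length, config, rng)
        if coords is not None:
            return coords
    raise RuntimeError(f"backbone generation failed for length {length}: "
                       "persistent self-collisions")


def _try_chain(length: int, config: SimConfig, rng) -> np.ndarray | None:
    coords = np.zeros((length, 3))
    for i in range(1, length):
        for _ in range(100):
            step = rng.standard_normal(3)
            step *= config.bond_length / np.linalg.norm(step)
            proposal = coords[i - 1] + step
            d = np.linalg.norm(coords[:i] - proposal, axis=1)
            # the predecessor sits exactly one bond away; it never collides
            if d[: i - 1].size == 0 or d[: i - 1].min() >= config.excluded_radius:
                coords[i] = proposal
                break
        else:
            return None
    return coords


def _term_direction(term: str, config: SimConfig) -> np.ndarray:
    """Fixed unit direction for a term's embedding shift (dataset-wide)."""
    digest = hashlib.sha256(f"{config.seed}:motif:{term}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little") % (2**63))
    v = rng.standard_normal(config.embedding_dim)
    return v / np.linalg.norm(v)


def generate_protein(config: SimConfig, seed: int,
                     protein_id: str | None = None) -> SyntheticProtein:
    """Draw one protein: backbone, embedding with motifs, GO and SL labels."""
    rng = np.random.default_rng(seed)
    length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    coords = generate_backbone(length, config, seed=int(rng.integers(2**31)))
    embedding = rng.standard_normal((length, config.embedding_dim))

    windows: dict[str, tuple[int, int]] = {}
    present: set[str] = set()
    for motif in config.motifs:
        if rng.random() >= motif.prevalence:
            continue
        if motif.length > length:
            warnings.warn(f"{motif.term}: motif length {motif.length} exceeds "
                          f"protein length {length}; term skipped", stacklevel=2)
            continue
        start = int(rng.integers(0, length - motif.length + 1))
        embedding[start : start + motif.length] += (
            motif.shift * _term_direction(motif.term, config)
        )
        windows[motif.term] = (start, start + motif.length)
        present.add(motif.term)

    def label_vector(ontology: str) -> np.ndarray:
        return np.array([1 if t in present else 0
                         for t in config.terms(ontology)], dtype=np.int8)

    sl = np.array([1 if rule.holds(present) else 0 for rule in config.sl_rules],
                  dtype=np.int8)
    flips = rng.random(sl.shape[0]) < config.label_noise
    sl = np.where(flips, 1 - sl, sl).astype(np.int8)

    record = ProteinRecord(
        id=protein_id or f"synth{seed:06d}", sequence=sequence, coords=coords,
        go_bp=label_vector("bp"), go_cc=label_vector("cc"),
        go_mf=label_vector("mf"), sl=sl)
    return SyntheticProtein(record=record, embedding=embedding,
                            motif_windows=windows, go_terms=present)


def generate_corpus(config: SimConfig) -> list[SyntheticProtein]:
    """Generate ``config.n_proteins`` proteins with per-protein seeds derived
    from the config seed."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31, size=config.n_proteins)
    return [generate_protein(config, int(s), protein_id=f"synth{i:05d}")
            for i, s in enumerate(seeds)]


def generate_dataset(config: SimConfig, out_dir) -> Path:
    """Write a dataset directory in the layout the I/O module expects.

    ``sequences.fasta``, ``coords/<id>.xyz``, ``embeddings/<id>.tsv``,
    ``labels_{bp,cc,mf,sl}.tsv``, ``motif_windows.tsv`` and a manifest
    recording the generating configuration and seed.
    """
    out = Path(out_dir)
    (out / "coords").mkdir(parents=True, exist_ok=True)
    (out / "embeddings").mkdir(exist_ok=True)
    proteins = generate_corpus(config)

    write_fasta([(p.record.id, p.record.sequence) for p in proteins],
                out / "sequences.fasta")
    for p in proteins:
        np.savetxt(out / "coords" / f"{p.record.id}.xyz", p.record.coords,
                   fmt="%.6f")
        np.savetxt(out / "embeddings" / f"{p.record.id}.tsv", p.embedding,
                   fmt="%.6f", delimiter="\t")

    for ontology in ("bp", "cc", "mf"):
        terms = config.terms(ontology)
        with open(out / f"labels_{ontology}.tsv", "w") as fh:
            for p in proteins:
                vec = getattr(p.record, f"go_{ontology}")
                for term, v in zip(terms, vec):
                    if v:
                        fh.write(f"{p.record.id}\t{term}\n")
    with open(out / "labels_sl.tsv", "w") as fh:
        for p in proteins:
            for cls, v in zip(config.sl_classes(), p.record.sl):
                if v:
                    fh.write(f"{p.record.id}\t{cls}\n")
    with open(out / "motif_windows.tsv", "w") as fh:
        fh.write("protein_id\tterm\tstart\tend\n")
        for p in proteins:
            for term, (a, b) in sorted(p.motif_windows.items()):
                fh.write(f"{p.record.id}\t{term}\t{a}\t{b}\n")

    manifest = {
        "seed": config.seed,
        "n_proteins": config.n_proteins,
        "length_range": list(config.length_range),
        "embedding_dim": config.embedding_dim,
        "bond_length": config.bond_length,
        "excluded_radius": config.excluded_radius,
        "label_noise": config.label_noise,
        "contact_threshold": config.contact_threshold,
        "terms": {o: config.terms(o) for o in ("bp", "cc", "mf")},
        "sl_classes": config.sl_classes(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
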