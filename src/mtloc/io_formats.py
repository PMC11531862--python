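"""Readers and writers for sequences, coordinates, labels and predictions.

File conventions
----------------
* Sequences: standard FASTA.
* Coordinates: PDB / mmCIF structure files (one Cα per residue, single
  chain) or plain whitespace-delimited ``x y z`` tables, one row per residue.
* Labels: two-column TSV ``protein_id<TAB>term`` (a row per annotation).
* Predictions: TSV ``protein_id  task  term  score`` with six decimals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SL_DEFAULT_CLASSES = 10
MAX_SEQUENCE_LENGTH = 1200

__all__ = [
    "ProteinRecord",
    "LabelVocabulary",
    "FormatError",
    "ConfigError",
    "read_fasta",
    "read_coords",
    "read_label_table",
    "build_vocabulary",
    "labels_to_matrix",
    "split_dataset",
    "write_predictions",
    "read_predictions",
]


class FormatError(ValueError):
    """An input file violates its format contract."""


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class ProteinRecord:
    """One protein: sequence, Cα coordinates and its label vectors.

    `go_bp`, `go_cc`, `go_mf` are binary vectors over the respective term
    vocabularies; `sl` is a binary vector over localization classes.
    """

    id: str
    sequence: str
    coords: np.ndarray
    go_bp: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    go_cc: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    go_mf: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    sl: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.sequence)
        if n < 1:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        if self.coords.shape[0] != n:
            raise FormatError(
                f"protein {self.id!r}: {n} residues but "
                f"{self.coords.shape[0]} coordinate rows"
            )
        for name in ("go_bp", "go_cc", "go_mf", "sl"):
            vec = np.asarray(getattr(self, name))
            if vec.size and not np.isin(vec, (0, 1)).all():
                raise FormatError(f"protein {self.id!r}: {name} is not binary")
            setattr(self, name, vec.astype(np.int8))

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered term list for one ontology (BP/CC/MF) or the SL classes.

    The order is fixed (lexicographic at construction) and persisted so that
    score-vector columns keep their meaning across runs.
    """

    ontology: str
    terms: tuple[str, ...]
    min_frequency: int = 1

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ConfigError(f"{self.ontology}: duplicate terms in vocabulary")

    def __len__(self) -> int:
        return len(self.terms)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


# -- sequences ----------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ordered ``(id, sequence)`` pairs.

    Sequences are uppercased; wrapped lines are rejoined.  Raises
    :class:`FormatError` (naming the offending line) on a record without a
    header or a header without sequence.
    """
    records: list[tuple[str, str]] = []
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current_id is not None:
                    if not chunks:
                        raise FormatError(
                            f"{path}: empty record {current_id!r} at line {header_line}"
                        )
                    records.append((current_id, "".join(chunks)))
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                if not current_id:
                    raise FormatError(f"{path}: malformed header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if current_id is None:
                    raise FormatError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                chunks.append(line.upper())
    if current_id is not None:
        if not chunks:
            raise FormatError(
                f"{path}: empty record {current_id!r} at line {header_line}"
            )
        records.append((current_id, "".join(chunks)))
    return records


def write_fasta(records: list[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- coordinates --------------------------------------------------------------

_STRUCTURE_SUFFIXES = {".pdb", ".ent", ".cif", ".mmcif"}


def read_coords(path) -> np.ndarray:
    """Read per-residue Cα coordinates (Å) as an n×3 array.

    Structure files (PDB/mmCIF, dispatched on extension) are reduced to the
    Cα trace of the first chain of the first model; residues lacking a Cα
    are dropped with a warning.  Any other extension is parsed as a plain
    whitespace-delimited ``x y z`` table.
    """
    path = Path(path)
    if path.suffix.lower() in _STRUCTURE_SUFFIXES:
        return _read_structure_ca(path)
    try:
        table = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: not a numeric xyz table ({exc})") from exc
    if table.size == 0 or table.shape[1] != 3:
        raise FormatError(f"{path}: expected three columns (x y z)")
    if not np.isfinite(table).all():
        raise FormatError(f"{path}: non-finite coordinates")
    return table


def _read_structure_ca(path: Path) -> np.ndarray:
    import gemmi

    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise FormatError(f"{path}: structure contains no models")
    model = structure[0]
    if len(model) == 0:
        raise FormatError(f"{path}: structure contains no chains")
    chain = model[0]
    if len(model) > 1:
        log.warning("%s: %d chains found; using the first (%s)",
                    path, len(model), chain.name)
    rows = []
    dropped = 0
    for residue in chain:
        ca = residue.find_atom("CA", "*")
        if ca is None:
            dropped += 1
            continue
        rows.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if dropped:
        log.warning("%s: dropped %d residues without a Calpha atom", path, dropped)
    if not rows:
        raise FormatError(f"{path}: no Calpha atoms found")
    return np.asarray(rows, dtype=float)


def pair_sequence_coords(sequence: str, coords: np.ndarray, pid: str = "?"):
    """Reconcile a sequence with its coordinate table by trimming to the
    shorter of the two (with a warning), mirroring the truncation applied to
    upstream per-residue features."""
    n_seq, n_xyz = len(sequence), coords.shape[0]
    if n_seq != n_xyz:
        n = min(n_seq, n_xyz)
        warnings.warn(
            f"protein {pid}: sequence length {n_seq} != coordinate rows {n_xyz}; "
            f"trimming both to {n}",
            stacklevel=2,
        )
        return sequence[:n], coords[:n]
    return sequence, coords


# -- labels -------------------------------------------------------------------

def read_label_table(path) -> pd.DataFrame:
    """Read a two-column TSV of (protein_id, term) annotation rows."""
    df = pd.read_csv(path, sep="\t", header=None, names=["protein_id", "term"],
                     dtype=str, comment="#")
    if df.empty:
        raise FormatError(f"{path}: empty label table")
    return df


def build_vocabulary(label_table: pd.DataFrame, min_frequency: int,
                     ontology: str = "GO") -> LabelVocabulary:
    """Retain terms annotated to at least `min_frequency` distinct proteins.

    Terms are sorted lexicographically.  Proteins whose every term falls
    below the threshold are reported via a warning, never silently dropped.
    """
    if min_frequency < 1:
        raise ConfigError("min_frequency must be >= 1")
    if label_table.empty:
        raise FormatError("empty label table")
    counts = label_table.drop_duplicates().groupby("term")["protein_id"].nunique()
    kept = sorted(counts.index[counts >= min_frequency])
    kept_set = set(kept)
    by_protein = label_table.groupby("protein_id")["term"].agg(set)
    orphans = [pid for pid, terms in by_protein.items() if not (terms & kept_set)]
    if orphans:
        warnings.warn(
            f"{ontology}: {len(orphans)} proteins retain no terms at "
            f"min_frequency={min_frequency} (e.g. {orphans[:3]})",
            stacklevel=2,
        )
    return LabelVocabulary(ontology=ontology, terms=tuple(kept),
                           min_frequency=min_frequency)


def labels_to_matrix(label_table: pd.DataFrame, protein_ids: list[str],
                     vocab: LabelVocabulary) -> np.ndarray:
    """Binary N×M matrix of annotations restricted to the vocabulary."""
    idx = vocab.index()
    row = {pid: i for i, pid in enumerate(protein_ids)}
    mat = np.zeros((len(protein_ids), len(vocab)), dtype=np.int8)
    for pid, term in label_table.itertuples(index=False):
        if pid in row and term in idx:
            mat[row[pid], idx[term]] = 1
    return mat


# -- dataset split ------------------------------------------------------------

def split_dataset(records: list, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Shuffle and partition into (train, valid, test).

    Sizes are the floor of each fraction of n, with the remainder assigned
    to the training split; the partition is disjoint, exhaustive and
    reproducible for a fixed seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions {fractions} do not sum to 1")
    n = len(records)
    if n < 3:
        raise ConfigError("dataset must contain at least 3 records")
    sizes = [int(np.floor(f * n)) for f in fractions]
    sizes[0] += n - sum(sizes)
    order = np.random.default_rng(seed).permutation(n)
    out, start = [], 0
    for size in sizes:
        out.append([records[i] for i in order[start : start + size]])
        start += size
    return tuple(out)


# -- predictions --------------------------------------------------------------

def write_predictions(scores: dict[str, dict[str, np.ndarray]],
                      vocabs: dict[str, LabelVocabulary], path) -> None:
    """Write per-protein score vectors as a deterministic TSV.

    `scores` maps protein_id -> task -> score vector; `vocabs` maps task
    (``bp``/``cc``/``mf``/``sl``) to its vocabulary.  Rows are ordered by
    (protein, task, term); scores are printed with six decimals and must be
    probabilities in [0, 1].
    """
    rows = []
    for pid in sorted(scores):
        for task in sorted(scores[pid]):
            vec = np.asarray(scores[pid][task], dtype=float)
            vocab = vocabs[task]
            if vec.shape != (len(vocab),):
                raise FormatError(
                    f"protein {pid} task {task}: score length {vec.shape} "
                    f"does not match vocabulary size {len(vocab)}"
                )
            if ((vec < 0) | (vec > 1)).any():
                raise FormatError(f"protein {pid} task {task}: scores outside [0,1]")
            for term, s in zip(vocab.terms, vec):
                rows.append((pid, task, term, f"{s:.6f}"))
    with open(path, "w") as fh:
        fh.write("protein_id\ttask\tterm\tscore\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "task": str,
                                            "term": str, "score": float})
    expected = ["protein_id", "task", "term", "score"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    return df
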