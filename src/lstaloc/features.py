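"""Sequence I/O and per-nucleotide physicochemical encoding.

Each residue is mapped to an 8-dimensional feature vector: one-hot identity
(A, T, C, G), the electron-ion interaction pseudopotential (EIIP), and the
three-bit nucleotide chemical property code (ring structure R, functional
group F, hydrogen bonding H). A sequence of length L becomes an L x 8 matrix;
no padding or truncation is ever applied.

EIIP values: A 0.1260, T 0.1335, C 0.1340, G 0.0806.
NCP triples:  A (1,1,1), C (0,1,0), G (1,0,0), T (0,0,1).
Ambiguous residues (N) encode as all-zero rows so downstream convolutions stay
well-defined without inventing feature values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LNCRNA_COMPARTMENTS",
    "MRNA_COMPARTMENTS",
    "MIN_SEQUENCE_LENGTH",
    "NucleotideSequence",
    "EncodedSequence",
    "LabelRecord",
    "sanitize_sequence",
    "read_fasta",
    "write_fasta",
    "encode_combined",
    "read_labels",
    "write_labels",
    "drop_exact_duplicates",
]

#: the five single-label lncRNA compartments, in canonical order
LNCRNA_COMPARTMENTS: tuple[str, ...] = ("Nucleus", "Exosome", "Cytoplasm", "Cytosol", "Ribosome")

#: the six multi-label mRNA compartments, in canonical order
MRNA_COMPARTMENTS: tuple[str, ...] = ("nucleus", "exosome", "cytosol", "ribosome", "membrane", "ER")

#: shortest admissible sequence — the largest convolution kernel in the encoder
MIN_SEQUENCE_LENGTH = 5

_EIIP = {"A": 0.1260, "T": 0.1335, "C": 0.1340, "G": 0.0806, "N": 0.0}
_NCP = {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "T": (0, 0, 1), "N": (0, 0, 0)}
_ONEHOT_ORDER = "ATCG"

# precomputed 5 x 8 row table indexed by A,C,G,T,N byte codes
_ROWS = np.zeros((256, 8), dtype=np.float32)
for _base in "ATCG":
    _row = np.zeros(8, dtype=np.float32)
    _row[_ONEHOT_ORDER.index(_base)] = 1.0
    _row[4] = _EIIP[_base]
    _row[5:8] = _NCP[_base]
    _ROWS[ord(_base)] = _row

_SANITIZE = bytes.maketrans(
    bytes(range(256)),
    bytes(
        ord(chr(c).upper().replace("U", "T"))
        if chr(c).upper() in "ACGTU"
        else ord("N")
        for c in range(256)
    ),
)


@dataclass(frozen=True)
class NucleotideSequence:
    """A named, sanitized nucleotide sequence over {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if set(self.residues) - set("ACGTN"):
            raise ValueError(f"sequence {self.id!r} contains unsanitized characters")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class EncodedSequence:
    """L x 8 feature matrix with fixed channel order.

    Channels: [onehot_A, onehot_T, onehot_C, onehot_G, EIIP, NCP_R, NCP_F, NCP_H].
    """

    id: str
    matrix: np.ndarray

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 8:
            raise ValueError("encoded matrix must be L x 8")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class LabelRecord:
    """A sequence id with a compartment name or a binary multi-label vector."""

    id: str
    label: str | None = None
    multilabel: tuple[int, ...] | None = None

    def __post_init__(self):
        if (self.label is None) == (self.multilabel is None):
            raise ValueError("exactly one of label / multilabel must be set")
        if self.multilabel is not None:
            if any(v not in (0, 1) for v in self.multilabel):
                raise ValueError(f"{self.id}: multi-label entries must be 0/1")
            if sum(self.multilabel) == 0:
                raise ValueError(f"{self.id}: multi-label vector is all zero")


def sanitize_sequence(raw: str) -> str:
    """Canonicalize to uppercase {A,C,G,T,N}: U -> T, anything else -> N."""
    if not raw:
        raise ValueError("cannot sanitize an empty sequence")
    return raw.encode("ascii", errors="replace").translate(_SANITIZE).decode("ascii")


def read_fasta(path: str | Path, min_length: int = MIN_SEQUENCE_LENGTH) -> list[NucleotideSequence]:
    """Read and sanitize a FASTA file; ids are headers up to first whitespace.

    Raises on missing/empty files, duplicate ids, and sequences shorter than
    ``min_length`` (no padding is performed anywhere downstream, so short
    sequences are rejected outright).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        residues = sanitize_sequence(str(rec.seq))
        if len(residues) < min_length:
            raise ValueError(
                f"sequence {rec.id!r} has length {len(residues)} < minimum {min_length}"
            )
        records.append(NucleotideSequence(id=rec.id, residues=residues))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, sequences: list[NucleotideSequence], width: int = 70) -> None:
    recs = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def encode_combined(seq: NucleotideSequence) -> EncodedSequence:
    """Encode a sanitized sequence into its L x 8 feature matrix."""
    codes = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    return EncodedSequence(id=seq.id, matrix=_ROWS[codes])


def read_labels(
    path: str | Path,
    mode: str = "single",
    classes: tuple[str, ...] | None = None,
    ids: list[str] | None = None,
) -> list[LabelRecord]:
    """Read a 2-column TSV (id, class) or (id, comma-separated 0/1 vector).

    The class vocabulary is fixed by ``classes`` (defaults to the lncRNA or
    mRNA compartment sets), never inferred from the file. When ``ids`` is
    given, the label ids must match it exactly (set equality).
    """
    if mode not in ("single", "multi"):
        raise ValueError(f"unknown label mode {mode!r}")
    if classes is None:
        classes = LNCRNA_COMPARTMENTS if mode == "single" else MRNA_COMPARTMENTS
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[LabelRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty label file {path}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, value = parts
            if sid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate id {sid!r}")
            seen.add(sid)
            if mode == "single":
                if value not in classes:
                    raise ValueError(
                        f"{path}:{lineno}: unknown class {value!r}; expected one of {classes}"
                    )
                records.append(LabelRecord(id=sid, label=value))
            else:
                bits = tuple(int(v) for v in value.split(","))
                if len(bits) != len(classes):
                    raise ValueError(
                        f"{path}:{lineno}: expected {len(classes)} binary entries, got {len(bits)}"
                    )
                records.append(LabelRecord(id=sid, multilabel=bits))
    if ids is not None and set(r.id for r in records) != set(ids):
        raise ValueError("label ids do not match the companion FASTA ids")
    return records


def write_labels(path: str | Path, records: list[LabelRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for r in records:
            if r.label is not None:
                fh.write(f"{r.id}\t{r.label}\n")
            else:
                fh.write(f"{r.id}\t{','.join(str(v) for v in r.multilabel)}\n")


def drop_exact_duplicates(sequences: list[NucleotideSequence]) -> list[NucleotideSequence]:
    """Keep the first occurrence of each distinct residue string."""
    seen: set[str] = set()
    out = []
    for s in sequences:
        if s.residues in seen:
            continue
        seen.add(s.residues)
        out.append(s)
    return out
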