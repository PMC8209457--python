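"""Sequence and distance-matrix file formats.

FASTA reading/writing goes through Biopython; the PHYLIP square distance
dialect (first line = taxon count, then one whitespace-separated row per
taxon) is written by hand because no installed library speaks it directly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix

__all__ = [
    "SequenceRecord",
    "Alignment",
    "read_fasta",
    "write_fasta",
    "read_phylip_square",
    "write_phylip_square",
]

#: residues accepted on ingest (uppercased); "." is treated like "-"
VALID_RESIDUES = set("ACGTUN-.")


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence row; residues are uppercased on construction."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """Ordered equal-length sequence rows (a multiple alignment)."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment must contain at least one sequence")
        length = len(records[0])
        if length == 0:
            raise ValueError("alignment length must be positive")
        for r in records:
            if len(r) != length:
                raise ValueError(
                    f"row {r.id!r} has length {len(r)}, expected {length}"
                )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes!r}")
        self.records = records

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_array(self) -> np.ndarray:
        """(n_rows, n_cols) array of single-byte residue codes."""
        return np.frombuffer(
            "".join(r.residues for r in self.records).encode("ascii"),
            dtype="S1",
        ).reshape(len(self), self.length)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, rejecting duplicate ids."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"empty sequence record in {path}: {rec.id!r}")
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


def read_phylip_square(path) -> DistanceMatrix:
    """Read a PHYLIP square (lower+upper) distance matrix.

    Raises on taxon-count mismatch, non-numeric cells, or asymmetry beyond
    1e-6 (the write precision).
    """
    text = Path(path).read_text()
    tokens = text.split()
    if not tokens:
        raise ValueError(f"empty distance file: {path}")
    try:
        n = int(tokens[0])
    except ValueError:
        raise ValueError(f"first token of {path} is not a taxon count: {tokens[0]!r}")
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise ValueError(
            f"{path}: expected {n} rows of {n} distances "
            f"({expected} tokens), found {len(tokens)} tokens"
        )
    ids = []
    data = np.empty((n, n))
    pos = 1
    for i in range(n):
        ids.append(tokens[pos])
        pos += 1
        for j in range(n):
            try:
                data[i, j] = float(tokens[pos])
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {tokens[pos]!r} at row "
                    f"{ids[-1]!r}, column {j}"
                )
            pos += 1
    if not np.allclose(data, data.T, atol=1e-6):
        raise ValueError(f"{path}: matrix is not symmetric")
    # symmetrise exactly so DistanceMatrix accepts write-precision rounding
    data = (data + data.T) / 2.0
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, ids)


def write_phylip_square(matrix: DistanceMatrix, path) -> None:
    """Write a DistanceMatrix in PHYLIP square format, 6 decimals."""
    with open(path, "w") as fh:
        fh.write(f"{matrix.shape[0]}\n")
        for name in matrix.ids:
            row = matrix[name]
            cells = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{name} {cells}\n")


def fasta_text(records: Iterable[SequenceRecord]) -> str:
    """FASTA serialisation to a string (used for byte-determinism checks)."""
    buf = _io.StringIO()
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=60)
    writer.write_file(seqs)
    return buf.getvalue()
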