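"""Sequence primitives, FASTA I/O and coordinate conventions.

All coordinates throughout the package are 0-based half-open on the plus
strand of the stored sequence.  Reverse-strand features are only ever stored
after explicit reverse-complementation.  Rendered reports use 1-based
inclusive coordinates and say so in their headers.

On ingestion ``U`` is normalized to ``T`` (viral RNA genomes are deposited
in the DNA alphabet) and residues are uppercased.  IUPAC ambiguity codes are
retained and never randomly resolved.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NUCLEOTIDE_ALPHABET",
    "PROTEIN_ALPHABET",
    "Interval",
    "SequenceRecord",
    "get_logger",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "translate",
]

#: IUPAC nucleotide codes (U accepted on input, normalized to T).
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
#: 20 amino acids plus X (unknown) and * (stop).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

_STRICT_NUC = frozenset("ACGT")

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def get_logger(name: str = "vivipart") -> logging.Logger:
    """Timestamped, leveled logger writing to standard error.

    Threshold values in effect are echoed at info level by the pipeline
    entry points so every run is auditable.
    """
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on the plus strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


def _infer_moltype(residues: str) -> str:
    return "nucleotide" if set(residues) <= NUCLEOTIDE_ALPHABET else "protein"


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence with an alphabet policy.

    ``residues`` are uppercased and, for nucleotide records, U-normalized on
    construction.  Every residue must belong to the declared alphabet; the
    first offending position is reported otherwise.
    """

    id: str
    residues: str
    description: str = ""
    moltype: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has empty residues")
        self.residues = self.residues.upper()
        if not self.moltype:
            self.moltype = _infer_moltype(self.residues)
        if self.moltype == "nucleotide":
            self.residues = self.residues.replace("U", "T")
            alphabet = NUCLEOTIDE_ALPHABET
        elif self.moltype == "protein":
            alphabet = PROTEIN_ALPHABET
        else:
            raise ValueError(f"unknown moltype {self.moltype!r}")
        for pos, char in enumerate(self.residues):
            if char not in alphabet:
                raise ValueError(
                    f"record {self.id!r}: residue {char!r} at position {pos} "
                    f"is outside the {self.moltype} alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, interval: Interval) -> str:
        if interval.end > len(self.residues):
            raise ValueError(
                f"interval end {interval.end} exceeds length {len(self.residues)}"
            )
        return self.residues[interval.start : interval.end]


def read_fasta(path, moltype: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into validated records, order preserved.

    Raises on an empty file, on duplicate ids (naming the id) and on
    residues outside the declared/inferred alphabet (with position).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip()
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc,
                           moltype=moltype)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns.

    Output bytes are deterministic for fixed input.
    """
    bio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(bio_records)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string, ambiguity codes included."""
    upper = seq.upper().replace("U", "T")
    if not set(upper) <= NUCLEOTIDE_ALPHABET:
        bad = sorted(set(upper) - NUCLEOTIDE_ALPHABET)
        raise ValueError(f"not a nucleotide sequence (offending residues {bad})")
    return str(Seq(upper).reverse_complement())


def translate(seq: str, frame: int = 0) -> str:
    """Translate ``seq`` in ``frame`` with the standard genetic code.

    Stops render as ``*``; the trailing partial codon is dropped; any codon
    containing an ambiguity code translates to ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    upper = seq.upper().replace("U", "T")
    out = []
    for i in range(frame, len(upper) - 2, 3):
        codon = upper[i : i + 3]
        if set(codon) <= _STRICT_NUC:
            out.append(_CODON_TABLE[codon])
        else:
            out.append("X")
    return "".join(out)
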