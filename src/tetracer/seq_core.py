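"""Sequence records, interval arithmetic, and elementary DNA operations.

All coordinates in this package are 0-based, half-open, on the plus strand.
Biological, TSS-relative promoter positions (e.g. "-2132", where -1 is the
base immediately upstream of the transcription start and +1 is the start
itself; there is no position 0) are converted with :func:`tss_to_offset`.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# IUPAC nucleotide codes -> set of concrete bases
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

#: minimal IUPAC code for every non-empty base set
IUPAC_OF_SET = {frozenset(v): k for k, v in IUPAC_SETS.items()}


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains characters outside the IUPAC DNA alphabet."""


def _validate_dna(seq: str, allow_gaps: bool = False) -> str:
    seq = seq.upper()
    allowed = set(IUPAC_SETS)
    if allow_gaps:
        allowed = allowed | {"-"}
    bad = set(seq) - allowed
    if bad:
        raise InvalidAlphabetError(
            f"non-IUPAC DNA character(s): {sorted(bad)!r} "
            "(RNA 'U' and protein letters are rejected)"
        )
    return seq


@dataclasses.dataclass
class SequenceRecord:
    """A named DNA sequence over the IUPAC alphabet (upper-cased on construction)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = _validate_dna(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """Half-open, 0-based interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement of *seq*; IUPAC ambiguity codes map to their complements."""
    seq = _validate_dna(seq, allow_gaps=True)
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def extract_subsequence(rec: SequenceRecord, iv: GenomicInterval) -> str:
    """Slice *rec* at *iv*; a minus-strand interval returns the reverse complement."""
    if iv.end > len(rec.seq):
        raise IndexError(
            f"interval [{iv.start}, {iv.end}) out of range for {rec.id} (len {len(rec.seq)})"
        )
    sub = rec.seq[iv.start : iv.end]
    return reverse_complement(sub) if iv.strand == "-" else sub


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff every base of *seq* is in the base set of the matching IUPAC code."""
    if len(pattern) != len(seq):
        raise ValueError(f"length mismatch: pattern {len(pattern)} vs seq {len(seq)}")
    pattern = _validate_dna(pattern)
    seq = _validate_dna(seq)
    return all(b in IUPAC_SETS[p] for p, b in zip(pattern, seq))


def tss_to_offset(position: int, tss_index: int) -> int:
    """Convert a biological TSS-relative position to a 0-based offset.

    ``tss_index`` is the 0-based index of the +1 base in the sequence.
    Position +1 maps to ``tss_index``; position -1 to ``tss_index - 1``.
    There is no biological position 0.
    """
    if position == 0:
        raise ValueError("biological TSS-relative coordinates have no position 0")
    return tss_index + position - 1 if position > 0 else tss_index + position


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file; sequences are upper-cased and validated."""
    return [
        SequenceRecord(r.id, str(r.seq), r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


_BED6_COLS = ["seq_id", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED (up to 6 columns) into a DataFrame with BED6 column names."""
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(_BED6_COLS)]
    df.columns = _BED6_COLS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    return df


def bed_to_intervals(df: pd.DataFrame) -> Iterator[GenomicInterval]:
    for row in df.itertuples(index=False):
        yield GenomicInterval(row.seq_id, int(row.start), int(row.end), row.strand)
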