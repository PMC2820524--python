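"""Pairwise comparison of paralogous promoter regions.

Two promoters descended from a recent duplication share a backbone that is
interrupted by large (here: >=200 bp) insertion/deletion "regions".  Each
region is either DNA *added* to the copy that carries it (typically a
transposable element, betrayed by multiple genomic copies) or single-copy
sequence *lost* from the other paralog.  This module aligns the pair,
segments the large indel regions, and classifies each region's origin by
counting its copies in the genome.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import pandas as pd
from Bio import Align

from .homology import SearchParams, count_copies
from .seq_core import GenomicInterval, SequenceRecord


@dataclasses.dataclass
class GlobalAlignment:
    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    score: float


@dataclasses.dataclass
class IndelRegion:
    id: str  # Roman numeral, ordered proximal -> distal
    carrier: str  # id of the sequence holding the extra DNA
    iv: GenomicInterval  # on the carrier
    length: int


@dataclasses.dataclass
class RegionClassification:
    region: IndelRegion
    copy_count: int
    call: str  # insertion_into_carrier | loss_from_other | ambiguous
    evidence: str


def align_promoters(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -0.5,
) -> GlobalAlignment:
    """Global affine-gap alignment (a gap of length L scores open + L*extend)."""
    if not a.seq or not b.seq:
        raise ValueError("both sequences must be nonempty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a.seq, b.seq)[0]
    return GlobalAlignment(a.id, b.id, str(aln[0]), str(aln[1]), float(aln.score))


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    out = []
    for v, s in _ROMAN:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' in an alignment row, as half-open column spans."""
    runs = []
    start = None
    for i, ch in enumerate(row):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def _merge_runs(runs: list[tuple[int, int]], join_dist: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < join_dist:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def segment_length_divergent_regions(
    alignment: GlobalAlignment,
    min_region_len: int = 200,
    join_dist: int = 50,
    proximal_end: str = "3prime",
) -> list[IndelRegion]:
    """Large indel regions of a promoter-pair alignment.

    Gap runs in one row mark extra DNA in the *other* (carrier) sequence.
    Runs in the same row closer than ``join_dist`` aligned columns are
    merged; merged runs whose total gap length is >= ``min_region_len``
    become regions, labelled with Roman numerals from the proximal end
    (``3prime`` by default: promoters are conventionally supplied 5'->3'
    ending at the transcription start)."""
    candidates = []  # (alignment column span, carrier row)
    for row, carrier_row in ((alignment.aligned_a, "b"), (alignment.aligned_b, "a")):
        for s, e in _merge_runs(_gap_runs(row), join_dist):
            gap_len = row[s:e].count("-")
            if gap_len >= min_region_len:
                candidates.append((s, e, carrier_row, gap_len))
    if proximal_end == "3prime":
        candidates.sort(key=lambda c: -c[0])
    else:
        candidates.sort(key=lambda c: c[0])
    regions = []
    for k, (s, e, carrier_row, gap_len) in enumerate(candidates, start=1):
        if carrier_row == "a":
            carrier_id = alignment.a_id
            carrier_aln = alignment.aligned_a
        else:
            carrier_id = alignment.b_id
            carrier_aln = alignment.aligned_b
        # carrier coordinates: count non-gap carrier characters before/within span
        start = sum(1 for ch in carrier_aln[:s] if ch != "-")
        extra = sum(1 for ch in carrier_aln[s:e] if ch != "-")
        regions.append(
            IndelRegion(
                id=roman(k),
                carrier=carrier_id,
                iv=GenomicInterval(carrier_id, start, start + extra),
                length=gap_len,
            )
        )
    return regions


def region_sequence(region: IndelRegion, carriers: dict[str, SequenceRecord]) -> SequenceRecord:
    rec = carriers[region.carrier]
    return SequenceRecord(
        f"region_{region.id}", rec.seq[region.iv.start : region.iv.end],
        f"{region.carrier}:{region.iv.start}-{region.iv.end}",
    )


def classify_region_origin(
    region: IndelRegion,
    region_seq: SequenceRecord,
    genome: Sequence[SequenceRecord],
    params: Optional[SearchParams] = None,
    min_copies_for_repeat: int = 2,
) -> RegionClassification:
    """Insertion vs loss by genomic copy number.

    >= ``min_copies_for_repeat`` copies: repetitive DNA that was inserted
    into the carrier.  Exactly 1 copy: single-copy sequence retained on the
    carrier and lost from the other paralog.  0 copies (degenerate, the
    region does not even match itself): ambiguous.
    """
    n, _hits = count_copies(region_seq, genome, params)
    if n >= min_copies_for_repeat:
        call = "insertion_into_carrier"
    elif n == 1:
        call = "loss_from_other"
    else:
        call = "ambiguous"
    evidence = (
        f"copy_count={n} (threshold {min_copies_for_repeat} for repeat call), "
        f"region length {region.length} bp on {region.carrier}"
    )
    return RegionClassification(region=region, copy_count=n, call=call, evidence=evidence)


def regions_to_table(classifications: Sequence[RegionClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.region.id,
                "carrier": c.region.carrier,
                "start": c.region.iv.start,
                "end": c.region.iv.end,
                "length": c.region.length,
                "copy_count": c.copy_count,
                "call": c.call,
            }
            for c in classifications
        ]
    )


def regions_to_gff3(regions: Sequence[IndelRegion], source: str = "tetracer") -> str:
    lines = ["##gff-version 3"]
    for r in regions:
        lines.append(
            "\t".join(
                [
                    r.carrier, source, "sequence_difference",
                    str(r.iv.start + 1), str(r.iv.end), ".", "+", ".",
                    f"ID=region_{r.id};length={r.length}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
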