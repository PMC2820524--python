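"""De-novo characterization of candidate class-II (cut-and-paste) elements.

A DNA transposon inserted by a cut-and-paste transposase is recognisable by
three structural hallmarks even when it carries no coding capacity:

* terminal inverted repeats (TIRs): the first bases of the element recur,
  reverse-complemented, at its other end;
* a target site duplication (TSD): the short host motif at the integration
  site is duplicated, so identical flanks abut the element on both sides;
* absence of a transposase open reading frame marks the element as
  non-autonomous (mobilised in trans by an autonomous relative).

This module detects the hallmarks, classifies the element, builds a
majority-rule consensus from aligned genomic copies, and re-joins an
element that was split in two by a secondary nested insertion.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from .seq_core import (
    IUPAC_OF_SET,
    IUPAC_SETS,
    GenomicInterval,
    SequenceRecord,
    iupac_match,
    reverse_complement,
)

#: terminal motif of the P-element superfamily, matched against the first 5 nt
TERMINAL_MOTIF = "YARNG"

_STOPS = {"TAA", "TAG", "TGA"}


@dataclasses.dataclass
class TirPair:
    """Terminal inverted repeat pair, with intervals on the element itself."""

    left_iv: GenomicInterval
    right_iv: GenomicInterval
    length: int
    mismatches: int


@dataclasses.dataclass
class TargetSiteDuplication:
    """Duplicated host motif flanking an insertion (intervals on the host)."""

    seq: str
    length: int
    left_iv: GenomicInterval
    right_iv: GenomicInterval


@dataclasses.dataclass
class AnnotatedElement:
    interval: GenomicInterval
    tir: Optional[TirPair] = None
    tsd: Optional[TargetSiteDuplication] = None
    terminal_motif_match: bool = False
    longest_orf_codons: int = 0
    classification: str = "unclassified"


@dataclasses.dataclass
class ConsensusModel:
    aligned_copies: list[str]
    threshold: float
    consensus: str


def find_tirs(
    element: str,
    min_len: int = 10,
    max_len: Optional[int] = None,
    max_mismatch: int = 0,
) -> Optional[TirPair]:
    """Longest terminal inverted repeat anchored at both element termini.

    Scans lengths from ``max_len`` (default: half the element) down to
    ``min_len`` and returns the first (= longest) prefix whose reverse
    complement equals the suffix with at most ``max_mismatch`` substitutions.
    """
    element = element.upper()
    n = len(element)
    if max_len is None:
        max_len = n // 2
    max_len = min(max_len, n // 2)
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    if n < 2 * min_len:
        raise ValueError(f"element of length {n} shorter than 2*min_len")
    for L in range(max_len, min_len - 1, -1):
        prefix = element[:L]
        rc_suffix = reverse_complement(element[-L:])
        mism = sum(a != b for a, b in zip(prefix, rc_suffix))
        if mism <= max_mismatch:
            return TirPair(
                left_iv=GenomicInterval("element", 0, L),
                right_iv=GenomicInterval("element", n - L, n),
                length=L,
                mismatches=mism,
            )
    return None


def find_tsd(
    host: SequenceRecord,
    element_iv: GenomicInterval,
    min_len: int = 2,
    max_len: int = 20,
) -> Optional[TargetSiteDuplication]:
    """Longest exact duplication immediately flanking ``element_iv`` in *host*.

    Returns the largest ``k`` in [min_len, max_len] with
    ``host[start-k:start] == host[end:end+k]``; matching is exact — the
    diagnostic duplication is a perfect copy made at integration time.
    """
    start, end = element_iv.start, element_iv.end
    if start < max_len or end + max_len > len(host.seq):
        raise ValueError(
            f"need >= {max_len} bp of flank on both sides of [{start}, {end})"
        )
    for k in range(max_len, min_len - 1, -1):
        left = host.seq[start - k : start]
        right = host.seq[end : end + k]
        if left == right:
            return TargetSiteDuplication(
                seq=left,
                length=k,
                left_iv=GenomicInterval(host.id, start - k, start),
                right_iv=GenomicInterval(host.id, end, end + k),
            )
    return None


def build_consensus(aligned_copies: Sequence[str], threshold: float = 0.5) -> ConsensusModel:
    """Majority-rule consensus of gapped, equal-length copies.

    Per column (n rows, gaps counted in every denominator):

    * gap fraction >= threshold        -> column dropped;
    * one base at frequency >= t       -> that base;
    * several bases at frequency >= t  -> minimal IUPAC code covering them;
    * no base reaches t                -> IUPAC code of all bases present.
    """
    if len(aligned_copies) < 2:
        raise ValueError("need at least 2 aligned copies")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    copies = [c.upper() for c in aligned_copies]
    width = len(copies[0])
    if any(len(c) != width for c in copies):
        raise ValueError("ragged alignment: copies differ in length")
    n = len(copies)
    out = []
    for j in range(width):
        column = [c[j] for c in copies]
        gaps = column.count("-")
        if gaps / n >= threshold:
            continue
        bases = [b for b in column if b != "-"]
        freqs = {b: bases.count(b) / n for b in set(bases)}
        at_thr = sorted(b for b, f in freqs.items() if f >= threshold)
        if len(at_thr) == 1:
            out.append(at_thr[0])
        elif at_thr:
            out.append(IUPAC_OF_SET[frozenset(at_thr)])
        else:
            out.append(IUPAC_OF_SET[frozenset(freqs)])
    return ConsensusModel(list(copies), threshold, "".join(out))


def longest_orf_span(seq: str) -> tuple[int, str, int]:
    """Longest ATG-to-stop ORF over all six frames.

    Returns ``(codons, strand, start)`` where *start* is the ATG offset on
    the reported strand ('+': input orientation, '-': its reverse
    complement); ``(0, '+', -1)`` if no terminated ORF exists.  Codon count
    includes the ATG and excludes the stop.
    """
    seq = seq.upper()
    best = (0, "+", -1)
    for strand, strand_seq in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            start = None
            for i in range(frame, len(strand_seq) - 2, 3):
                codon = strand_seq[i : i + 3]
                if codon in _STOPS:
                    if start is not None:
                        codons = (i - start) // 3
                        if codons > best[0]:
                            best = (codons, strand, start)
                        start = None
                elif codon == "ATG" and start is None:
                    start = i
    return best


def longest_orf(seq: str) -> int:
    """Length in codons (ATG included, stop excluded) of the longest ATG-to-stop
    open reading frame over all six frames; ORFs must terminate with a stop."""
    return longest_orf_span(seq)[0]


def _has_polya_tail(seq: str, min_run: int = 8) -> bool:
    """Terminal poly-A on either strand: a trailing A-run or leading T-run."""
    seq = seq.upper()
    trailing_a = len(seq) - len(seq.rstrip("A"))
    leading_t = len(seq) - len(seq.lstrip("T"))
    return trailing_a >= min_run or leading_t >= min_run


def classify_element(el: AnnotatedElement, element_seq: str, orf_min_codons: int = 100) -> str:
    """Decision table over recorded structural features.

    TIR + TSD, no long ORF      -> nonautonomous_class_II
    TIR + TSD, ORF >= threshold -> class_II_autonomous (carries its transposase)
    no TIR, terminal poly-A     -> class_I_like (retroelement signature)
    otherwise                   -> unclassified
    """
    if el.tir is not None and el.tsd is not None:
        if el.longest_orf_codons >= orf_min_codons:
            return "class_II_autonomous"
        return "nonautonomous_class_II"
    if el.tir is None and _has_polya_tail(element_seq):
        return "class_I_like"
    return "unclassified"


def annotate_element(
    host: SequenceRecord,
    element_iv: GenomicInterval,
    tir_min_len: int = 10,
    tir_max_mismatch: int = 0,
    tsd_min_len: int = 2,
    tsd_max_len: int = 20,
    orf_min_codons: int = 100,
) -> AnnotatedElement:
    """Run the full hallmark scan on one candidate element in its host context."""
    element_seq = host.seq[element_iv.start : element_iv.end]
    el = AnnotatedElement(interval=element_iv)
    try:
        el.tir = find_tirs(element_seq, min_len=tir_min_len, max_mismatch=tir_max_mismatch)
    except ValueError:
        el.tir = None
    try:
        el.tsd = find_tsd(host, element_iv, min_len=tsd_min_len, max_len=tsd_max_len)
    except ValueError:
        el.tsd = None
    el.longest_orf_codons = longest_orf(element_seq)
    el.terminal_motif_match = len(element_seq) >= len(TERMINAL_MOTIF) and iupac_match(
        TERMINAL_MOTIF, element_seq[: len(TERMINAL_MOTIF)]
    )
    el.classification = classify_element(el, element_seq, orf_min_codons=orf_min_codons)
    return el


def reconstruct_split_element(
    host: SequenceRecord,
    outer_parts: tuple[GenomicInterval, GenomicInterval],
    inner_iv: Optional[GenomicInterval] = None,
    rec_id: str = "reconstructed",
) -> SequenceRecord:
    """Re-join an element split by a nested insertion.

    Concatenates the two outer part sequences (the inner, younger element —
    and its own TSD copy if the caller excluded it from the parts — is
    simply absent from the result). The parts must not overlap and the
    inner interval, if given, must lie between them.
    """
    p1, p2 = sorted(outer_parts, key=lambda iv: iv.start)
    if p1.overlaps(p2):
        raise ValueError("outer parts overlap")
    if inner_iv is not None and not (p1.end <= inner_iv.start and inner_iv.end <= p2.start):
        raise ValueError("inner interval does not lie between the outer parts")
    seq = host.seq[p1.start : p1.end] + host.seq[p2.start : p2.end]
    return SequenceRecord(rec_id, seq, f"rejoined {p1.start}-{p1.end} + {p2.start}-{p2.end}")


def element_gff3(host_id: str, el: AnnotatedElement, source: str = "tetracer") -> str:
    """GFF3 lines for an annotated element (element, TIR and TSD features)."""
    lines = ["##gff-version 3"]

    def row(ftype, iv, attrs):
        return "\t".join(
            [host_id, source, ftype, str(iv.start + 1), str(iv.end), ".", iv.strand, ".", attrs]
        )

    lines.append(
        row(
            "mobile_genetic_element",
            el.interval,
            f"ID=element1;classification={el.classification};"
            f"longest_orf_codons={el.longest_orf_codons};"
            f"terminal_motif_match={str(el.terminal_motif_match).lower()}",
        )
    )
    if el.tir is not None:
        off = el.interval.start
        for side, iv in (("left", el.tir.left_iv), ("right", el.tir.right_iv)):
            shifted = GenomicInterval(host_id, iv.start + off, iv.end + off)
            lines.append(
                row("terminal_inverted_repeat", shifted, f"Parent=element1;side={side}")
            )
    if el.tsd is not None:
        for side, iv in (("left", el.tsd.left_iv), ("right", el.tsd.right_iv)):
            lines.append(
                row(
                    "target_site_duplication",
                    iv,
                    f"Parent=element1;side={side};seq={el.tsd.seq}",
                )
            )
    return "\n".join(lines) + "\n"


def anchor_align_copies(reference: str, copies: Sequence[str]) -> list[str]:
    """Project each copy onto reference coordinates by global alignment.

    Returns equal-length rows (one per copy, length = len(reference)):
    copy residues at the reference columns they align to, '-' where the
    copy is deleted; copy insertions relative to the reference are dropped.
    Suitable input for :func:`build_consensus` when no multiple aligner is
    wanted (reference-anchored alignment).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.5
    aligner.extend_gap_score = -0.5
    rows = []
    for copy in copies:
        aln = aligner.align(reference, copy)[0]
        row = ["-"] * len(reference)
        ref_blocks, copy_blocks = aln.aligned
        for (rs, re_), (cs, ce) in zip(ref_blocks, copy_blocks):
            for k in range(re_ - rs):
                row[rs + k] = copy[cs + k]
        rows.append("".join(row))
    return rows


def refine_element_boundaries(
    host: SequenceRecord,
    iv: GenomicInterval,
    max_shift: int = 20,
    tir_min_len: int = 10,
    tir_max_len: int = 60,
    tir_max_mismatch: int = 0,
) -> GenomicInterval:
    """Trim an approximate element interval to the TIR-bearing core.

    Alignment-derived indel regions include the duplicated target site on
    one side of the true element, so the TIRs are not at the interval
    termini.  Scans inward trims of up to ``max_shift`` bp at each end and
    returns the interval with the longest detectable TIR (ties: smallest
    total trim); the input interval is returned unchanged if no trim
    exposes a TIR.
    """
    best = None
    seq = host.seq
    for ds in range(0, max_shift + 1):
        for de in range(0, max_shift + 1):
            s, e = iv.start + ds, iv.end - de
            if e - s < 2 * tir_min_len:
                continue
            try:
                tir = find_tirs(
                    seq[s:e], min_len=tir_min_len, max_len=tir_max_len,
                    max_mismatch=tir_max_mismatch,
                )
            except ValueError:
                continue
            if tir is None:
                continue
            key = (-tir.length, ds + de, ds)
            if best is None or key < best[0]:
                best = (key, GenomicInterval(iv.seq_id, s, e, iv.strand))
    return best[1] if best is not None else iv
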