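"""BLASTN-like seed-and-extend homology search and genomic copy counting.

Used to count how many times an element occurs in a genome under an
identity/coverage filter (default: >=85% identity over >=85% of the query,
the classic criterion for calling two repeat copies members of one family),
and to report the features flanking each hit.

Extension strategy: exact-word seeds are clustered by diagonal, and each
cluster is aligned with an optimal local (Smith-Waterman, affine-gap)
dynamic program on a window around the cluster, rather than with a greedy
x-drop walk; the ``x_drop`` parameter bounds the window padding.  On
desk-scale subjects this guarantees the best hit attains the true local
optimum for the scoring scheme.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import pandas as pd

from . import _align
from .seq_core import GenomicInterval, SequenceRecord, reverse_complement


@dataclasses.dataclass
class SearchParams:
    word_size: int = 11
    min_identity: float = 0.85
    min_coverage: float = 0.85
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    x_drop: float = 20.0
    strict_gt: bool = False  # use > instead of >= for the identity/coverage filter

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")


@dataclasses.dataclass
class AlignmentHit:
    query_iv: GenomicInterval
    subject_iv: GenomicInterval
    identity: float
    coverage: float
    score: float
    aligned_pairs: str  # CIGAR over query (M/D=query-only/I=subject-only)


def recompute_hit_stats(
    hit: "AlignmentHit", query: SequenceRecord, subject: SequenceRecord
) -> tuple[float, float]:
    """Identity and coverage re-derived from the hit's CIGAR and the sequences
    (independent consistency check against the stored values)."""
    if hit.subject_iv.strand == "+":
        qseq, qs = query.seq, hit.query_iv.start
    else:
        qseq = reverse_complement(query.seq)
        qs = len(query.seq) - hit.query_iv.end
    cols, matches, qcols = _cigar_stats(
        hit.aligned_pairs, qseq, subject.seq, qs, hit.subject_iv.start, qseq
    )
    return matches / cols, qcols / len(query.seq)


def _seed_positions(query: str, subject: str, w: int) -> dict[int, list[tuple[int, int]]]:
    """Exact w-mer matches grouped by diagonal (subject_pos - query_pos)."""
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - w + 1):
        index.setdefault(subject[j : j + w], []).append(j)
    diags: dict[int, list[tuple[int, int]]] = {}
    for i in range(len(query) - w + 1):
        word = query[i : i + w]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            diags.setdefault(j - i, []).append((i, j))
    return diags


def _cluster_diagonals(
    diags: dict[int, list[tuple[int, int]]], qlen: int, band: int = 100
):
    """Group seeds into candidate hit regions on the subject.

    Seeds belong to one candidate when their diagonals differ by at most
    ``band`` (indel drift within one alignment) *and* their subject
    positions are not separated by more than the query length (distinct
    copies of the query never merge).  Returns subject (lo, hi) spans.
    """
    if not diags:
        return []
    items = sorted(diags.items())
    diag_groups: list[list[tuple[int, int]]] = []
    cur_d = None
    cur: list[tuple[int, int]] = []
    for d, seeds in items:
        if cur_d is None or d - cur_d <= band:
            cur.extend(seeds)
        else:
            diag_groups.append(cur)
            cur = list(seeds)
        cur_d = d
    diag_groups.append(cur)
    # two-hit style noise filter: a genuine homologue of a long query seeds
    # densely, so sparse clusters are skipped for long queries
    min_seeds = max(1, qlen // 300)
    regions = []
    for seeds in diag_groups:
        seeds = sorted(seeds, key=lambda s: s[1])
        cluster = [seeds[0]]
        for seed in seeds[1:]:
            if seed[1] - cluster[-1][1] > qlen:
                if len(cluster) >= min_seeds:
                    regions.append((cluster[0][1], cluster[-1][1]))
                cluster = []
            cluster.append(seed)
        if len(cluster) >= min_seeds:
            regions.append((cluster[0][1], cluster[-1][1]))
    if not regions:
        return []
    # merge overlapping spans arising from different diagonal groups
    regions.sort()
    merged = [regions[0]]
    for lo, hi in regions[1:]:
        plo, phi = merged[-1]
        if lo <= phi:
            merged[-1] = (plo, max(phi, hi))
        else:
            merged.append((lo, hi))
    return merged


def _align_window(query_enc, subject_enc, lo, hi, qlen, params: SearchParams):
    # pad with what the seed span leaves uncovered, plus slack for gaps
    pad = max(0, qlen - (hi - lo)) + int(params.x_drop) + params.word_size
    ws = max(0, lo - pad)
    we = min(len(subject_enc), hi + params.word_size + pad)
    res = _align.smith_waterman(
        query_enc,
        subject_enc[ws:we],
        params.match,
        params.mismatch,
        params.gap_open,
        params.gap_extend,
    )
    if res is None:
        return None
    score, qs, qe, ss, se, cigar = res
    return score, qs, qe, ws + ss, ws + se, cigar


def _cigar_stats(cigar: str, query, subject, qs, ss, strand_query: str):
    """Alignment columns, matches and query columns from a CIGAR walk."""
    cols = matches = qcols = 0
    i, j = qs, ss
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
            continue
        k = int(n)
        n = ""
        cols += k
        if ch == "M":
            for _ in range(k):
                if strand_query[i] == subject[j]:
                    matches += 1
                i += 1
                j += 1
            qcols += k
        elif ch == "D":
            i += k
            qcols += k
        else:  # I
            j += k
    return cols, matches, qcols


def seed_and_extend(
    query: SequenceRecord,
    subject: SequenceRecord,
    params: Optional[SearchParams] = None,
) -> list[AlignmentHit]:
    """Local hits of *query* in *subject* on both strands.

    Hits are sorted by score descending, ties by subject start ascending.
    """
    params = params or SearchParams()
    if len(query.seq) < params.word_size:
        raise ValueError("query shorter than word_size")
    if not subject.seq:
        return []
    qlen = len(query.seq)
    hits: list[AlignmentHit] = []
    subject_enc = _align.encode(subject.seq)
    for strand in "+-":
        qseq = query.seq if strand == "+" else reverse_complement(query.seq)
        query_enc = _align.encode(qseq)
        diags = _seed_positions(qseq, subject.seq, params.word_size)
        regions = _cluster_diagonals(diags, qlen)
        seen: set[tuple[int, int]] = set()
        for lo, hi in regions:
            res = _align_window(query_enc, subject_enc, lo, hi, qlen, params)
            if res is None:
                continue
            score, qs, qe, ss, se, cigar = res
            if (ss, se) in seen:
                continue
            seen.add((ss, se))
            cols, matches, qcols = _cigar_stats(cigar, qseq, subject.seq, qs, ss, qseq)
            if cols == 0:
                continue
            identity = matches / cols
            coverage = qcols / qlen
            if strand == "+":
                q_iv = GenomicInterval(query.id, qs, qe, "+")
            else:
                q_iv = GenomicInterval(query.id, qlen - qe, qlen - qs, "-")
            hits.append(
                AlignmentHit(
                    query_iv=q_iv,
                    subject_iv=GenomicInterval(subject.id, ss, se, strand),
                    identity=identity,
                    coverage=coverage,
                    score=score,
                    aligned_pairs=cigar,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.subject_iv.start))
    return hits


def _passes(hit: AlignmentHit, params: SearchParams) -> bool:
    if params.strict_gt:
        return hit.identity > params.min_identity and hit.coverage > params.min_coverage
    return hit.identity >= params.min_identity and hit.coverage >= params.min_coverage


def count_copies(
    query: SequenceRecord,
    genome: Sequence[SequenceRecord],
    params: Optional[SearchParams] = None,
) -> tuple[int, list[AlignmentHit]]:
    """Number of non-overlapping genomic copies passing the identity/coverage
    filter; overlapping passing hits collapse to the best-scoring one."""
    params = params or SearchParams()
    passing: list[AlignmentHit] = []
    for rec in genome:
        passing.extend(h for h in seed_and_extend(query, rec, params) if _passes(h, params))
    passing.sort(key=lambda h: (-h.score, h.subject_iv.seq_id, h.subject_iv.start))
    kept: list[AlignmentHit] = []
    for hit in passing:
        iv = GenomicInterval(hit.subject_iv.seq_id, hit.subject_iv.start, hit.subject_iv.end)
        if any(
            iv.overlaps(GenomicInterval(k.subject_iv.seq_id, k.subject_iv.start, k.subject_iv.end))
            for k in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.subject_iv.seq_id, h.subject_iv.start))
    return len(kept), kept


def flanking_context(
    hits: Sequence[AlignmentHit],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Nearest feature up- and downstream of each hit (signed distances).

    *features* is a BED-like DataFrame (``seq_id start end name``).  Distance
    0 means the hit overlaps the feature; upstream distances are negative.
    An empty row (NA) is emitted when the hit's sequence carries no feature.
    """
    rows = []
    for hit in hits:
        sid, s, e = hit.subject_iv.seq_id, hit.subject_iv.start, hit.subject_iv.end
        sub = features[features["seq_id"] == sid]
        up_name = down_name = None
        up_dist = down_dist = None
        for f in sub.itertuples(index=False):
            if f.start < e and s < f.end:  # overlap: distance 0 on both sides
                up_name, up_dist = f.name, 0
                down_name, down_dist = f.name, 0
            elif f.end <= s:
                d = s - f.end
                if up_dist is None or (up_dist != 0 and d < abs(up_dist)):
                    up_name, up_dist = f.name, -d
            else:
                d = f.start - e
                if down_dist is None or (down_dist != 0 and d < down_dist):
                    down_name, down_dist = f.name, d
        rows.append(
            {
                "seq_id": sid,
                "start": s,
                "end": e,
                "upstream_feature": up_name,
                "upstream_distance": up_dist,
                "downstream_feature": down_name,
                "downstream_distance": down_dist,
            }
        )
    return pd.DataFrame(rows)


def hits_to_table(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    """Tabular (outfmt-6-like) view of a hit list."""
    return pd.DataFrame(
        [
            {
                "qid": h.query_iv.seq_id,
                "sid": h.subject_iv.seq_id,
                "identity": round(h.identity, 4),
                "length": h.subject_iv.end - h.subject_iv.start,
                "qstart": h.query_iv.start,
                "qend": h.query_iv.end,
                "sstart": h.subject_iv.start,
                "send": h.subject_iv.end,
                "strand": h.subject_iv.strand,
                "coverage": round(h.coverage, 4),
                "score": h.score,
                "cigar": h.aligned_pairs,
            }
            for h in hits
        ]
    )


def hits_to_bed(hits: Sequence[AlignmentHit]) -> str:
    lines = [
        "\t".join(
            [
                h.subject_iv.seq_id,
                str(h.subject_iv.start),
                str(h.subject_iv.end),
                h.query_iv.seq_id,
                str(int(h.score)),
                h.subject_iv.strand,
            ]
        )
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
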