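"""Seeded generators for every pipeline input, with known ground truth.

The generators emulate the study system: a pair of paralogous promoters
separated by large insertions, a genome carrying diverged copies of a
TIR/TSD-bearing element, clock-evolved neutral alignments over a species
tree containing a gene duplication and a later element insertion, and
planted binding-site instances.  Every generator takes a seed and derives
an independent RNG stream from (seed, operation name), so adding a
generator never perturbs existing outputs; results are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import brentq

from .annotation import find_tsd, longest_orf_span
from .seq_core import GenomicInterval, SequenceRecord, reverse_complement

BASES = np.array(list("ACGT"))
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# transition partner; transversion partners (two per base)
_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TRANSVERSION1 = np.array([1, 0, 1, 0])  # A->C, C->A, G->C, T->A
_TRANSVERSION2 = np.array([3, 2, 3, 2])  # A->T, C->G, G->T, T->G


def _rng(seed: int, operation: str) -> np.random.Generator:
    """Independent stream per (seed, operation name)."""
    return np.random.default_rng([seed, zlib.crc32(operation.encode())])


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


@dataclasses.dataclass
class TruthRecord:
    """Ground truth serialized alongside every generated dataset."""

    kind: str
    seed: int
    data: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# K2P sequence evolution


def k2p_proportions(d: float, kappa_ratio: float = 2.0) -> tuple[float, float]:
    """Expected transition/transversion proportions (P, Q) with P = R*Q whose
    K2P distance equals *d* (the generative inverse of the estimator)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if d == 0:
        return 0.0, 0.0
    R = kappa_ratio

    def f(q):
        return -0.5 * np.log(1 - (2 * R + 1) * q) - 0.25 * np.log(1 - 2 * q) - d

    q_max = (1.0 / (2 * R + 1)) * (1 - 1e-12)
    try:
        q = brentq(f, 1e-15, q_max)
    except ValueError as err:
        raise ValueError(f"distance d={d} beyond saturation for ts:tv={R}") from err
    return R * q, q


def evolve_sequence_k2p(
    seq: str,
    d: float,
    kappa_ratio: float = 2.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Mutate *seq* site-independently so the expected K2P distance is *d*.

    Each ACGT site undergoes a transition with probability P and each of the
    two transversions with probability Q/2, where (P, Q) solve the K2P
    expectations for *d* at the given ts:tv ratio.  Non-ACGT characters are
    left untouched.  Saturation bound: d <= 1.
    """
    if d > 1.0:
        raise ValueError("d > 1 is beyond the supported saturation bound")
    if rng is None:
        rng = _rng(0 if seed is None else seed, "evolve_sequence_k2p")
    if d == 0:
        return seq
    P, Q = k2p_proportions(d, kappa_ratio)
    codes = np.array([_CODE.get(c, -1) for c in seq.upper()])
    u = rng.random(len(codes))
    out = codes.copy()
    mutable = codes >= 0
    safe = np.where(mutable, codes, 0)
    out = np.where(mutable & (u < P), _TRANSITION[safe], out)
    out = np.where(mutable & (u >= P) & (u < P + Q / 2), _TRANSVERSION1[safe], out)
    out = np.where(mutable & (u >= P + Q / 2) & (u < P + Q), _TRANSVERSION2[safe], out)
    chars = np.array(list(seq.upper()))
    chars[mutable] = BASES[out[mutable]]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Elements in a genome


def make_tir_element(
    length: int,
    tir: str = "CAATGAGTTATATCACTAGAGGAGACA",
    seed: int = 0,
    gc: float = 0.5,
    max_orf_codons: int = 50,
) -> str:
    """Random element of *length* bp whose termini are *tir* and its reverse
    complement (a minimal non-autonomous class-II structural mock).

    A non-autonomous element carries no coding capacity, so interior ORFs
    longer than ``max_orf_codons`` are disrupted by planting a stop codon
    mid-ORF (the termini are never edited); pass ``max_orf_codons=None``
    to skip the screen.
    """
    if length < 2 * len(tir):
        raise ValueError("element shorter than twice the TIR")
    rng = _rng(seed, "make_tir_element")
    interior = random_dna(rng, length - 2 * len(tir), gc)
    seq = tir + interior + reverse_complement(tir)
    t = len(tir)
    n = len(seq)

    def break_extension(s):
        # ensure the inverted repeat stops at exactly len(tir): base t must
        # not pair with base n-1-t
        if s[t] == reverse_complement(s[n - 1 - t]):
            for b in "ACGT":
                if b != s[t] and b != reverse_complement(s[n - 1 - t]):
                    return s[:t] + b + s[t + 1 :]
        return s

    if max_orf_codons is None:
        return break_extension(seq)
    for _ in range(200):
        codons, strand, start = longest_orf_span(seq)
        if codons < max_orf_codons:
            seq2 = break_extension(seq)
            if seq2 == seq and longest_orf_span(seq2)[0] < max_orf_codons:
                break
            seq = seq2
            if longest_orf_span(seq)[0] < max_orf_codons:
                break
            continue
        mid = start + 3 * (codons // 2)  # codon-aligned position inside the ORF
        if strand == "+":
            pos, stop = mid, "TAA"
        else:
            pos, stop = n - mid - 3, reverse_complement("TAA")
        pos = min(max(pos, t + 3), n - t - 6)
        seq = seq[:pos] + stop + seq[pos + 3 :]
    return seq


def plant_element_copy_groups(
    backbone: SequenceRecord,
    element: str,
    groups: Sequence[tuple[int, float]],
    tsd_len: int = 8,
    kappa_ratio: float = 2.0,
    seed: int = 0,
    genome_id: str = "genome",
    max_attempts: int = 200,
) -> tuple[SequenceRecord, TruthRecord]:
    """Insert evolved element copies, each with a genuine target-site
    duplication, at non-overlapping backbone positions.

    *groups* is a list of (n_copies, divergence) pairs (e.g. true copies
    plus heavily diverged decoys).  Each insertion duplicates the
    ``tsd_len``-bp host motif at the integration site; positions where the
    flanking context would let the duplication extend beyond ``tsd_len``
    (or truncate it) are re-drawn, so detection truth is exact.
    """
    rng = _rng(seed, "plant_element_copies")
    host = backbone.seq
    n_total = sum(n for n, _ in groups)
    min_gap = tsd_len + 50  # keep planted copies clearly separated on the host
    placements = []  # (backbone position, divergence, group index)
    for gi, (n, div) in enumerate(groups):
        for _ in range(n):
            placements.append((div, gi))
    # draw distinct, well-separated backbone positions
    for attempt in range(max_attempts):
        positions = np.sort(
            rng.choice(
                np.arange(tsd_len + 1, len(host) - tsd_len - 1),
                size=n_total,
                replace=False,
            )
        )
        if n_total <= 1 or np.diff(positions).min() > min_gap:
            break
    else:
        raise RuntimeError("could not place copies without overlap")
    order = rng.permutation(n_total)
    chosen = [placements[i] for i in order]
    pieces = []
    truth_copies = []
    prev = 0
    offset = 0
    genome_positions = []
    for pos, (div, gi) in zip(positions, chosen):
        tsd = host[pos : pos + tsd_len]
        copy = evolve_sequence_k2p(element, div, kappa_ratio, rng=rng)
        pieces.append(host[prev : pos + tsd_len])  # ...target site (left copy)
        insert_at = pos + tsd_len + offset  # genome coordinate of copy start
        pieces.append(copy + tsd)  # element + duplicated target site
        truth_copies.append(
            {
                "backbone_pos": int(pos),
                "genome_start": int(insert_at),
                "genome_end": int(insert_at + len(copy)),
                "divergence": float(div),
                "group": int(gi),
                "tsd": tsd,
            }
        )
        genome_positions.append((insert_at, insert_at + len(copy)))
        offset += len(copy) + tsd_len
        prev = pos + tsd_len
    pieces.append(host[prev:])
    genome = SequenceRecord(genome_id, "".join(pieces), f"seed={seed}")
    # screen: every planted TSD must be detected at exactly tsd_len
    for (s, e), tc in zip(genome_positions, truth_copies):
        found = find_tsd(genome, GenomicInterval(genome.id, s, e), min_len=2, max_len=tsd_len + 4)
        if found is None or found.length != tsd_len:
            # rare flank collision: recurse with a perturbed stream
            return plant_element_copy_groups(
                backbone, element, groups, tsd_len, kappa_ratio, seed + 7919,
                genome_id, max_attempts,
            )
    truth = TruthRecord(
        kind="planted_element_copies",
        seed=seed,
        data={"tsd_len": tsd_len, "element_len": len(element), "copies": truth_copies},
    )
    return genome, truth


def plant_element_copies(
    backbone: SequenceRecord,
    element: str,
    n_copies: int,
    copy_divergence: float,
    tsd_len: int = 8,
    seed: int = 0,
    **kwargs,
) -> tuple[SequenceRecord, TruthRecord]:
    """Single-family convenience wrapper around plant_element_copy_groups."""
    if n_copies == 0:
        return (
            SequenceRecord(backbone.id, backbone.seq, backbone.description),
            TruthRecord("planted_element_copies", seed,
                        {"tsd_len": tsd_len, "element_len": len(element), "copies": []}),
        )
    return plant_element_copy_groups(
        backbone, element, [(n_copies, copy_divergence)], tsd_len, seed=seed, **kwargs
    )


# ---------------------------------------------------------------------------
# Promoter pairs


def generate_promoter_pair(
    backbone_len: int,
    region_spec: Sequence[tuple[str, int]],
    seed: int = 0,
    ids: tuple[str, str] = ("promA", "promY"),
    min_spacing: int = 300,
) -> tuple[SequenceRecord, SequenceRecord, TruthRecord]:
    """Two promoters sharing a random backbone, with large carrier-specific
    insertions at distinct positions.

    *region_spec* lists (carrier, length) pairs where carrier is 'A' or 'Y'
    (first or second id).  Truth records carrier, backbone position,
    carrier coordinates, and the inserted sequence id order.
    """
    rng = _rng(seed, "generate_promoter_pair")
    backbone = random_dna(rng, backbone_len)
    n = len(region_spec)
    if n == 0:
        a = SequenceRecord(ids[0], backbone)
        y = SequenceRecord(ids[1], backbone)
        return a, y, TruthRecord("promoter_pair", seed, {"backbone_len": backbone_len, "regions": []})
    lo, hi = min_spacing, backbone_len - min_spacing
    for _ in range(200):
        positions = np.sort(rng.choice(np.arange(lo, hi), size=n, replace=False))
        if n == 1 or np.diff(positions).min() >= min_spacing:
            break
    else:
        raise RuntimeError("backbone too short for requested regions")
    inserts = []
    for (carrier, length), pos in zip(region_spec, positions):
        if carrier not in ("A", "Y"):
            raise ValueError("carrier must be 'A' or 'Y'")
        if length >= backbone_len:
            raise ValueError("region longer than backbone")
        inserts.append({"carrier": carrier, "backbone_pos": int(pos),
                        "length": int(length), "seq": random_dna(rng, length)})
    truth_regions = []
    seqs = {}
    for carrier, rec_id in (("A", ids[0]), ("Y", ids[1])):
        pieces = []
        prev = 0
        offset = 0
        for ins in inserts:
            if ins["carrier"] != carrier:
                continue
            pos = ins["backbone_pos"]
            pieces.append(backbone[prev:pos])
            truth_regions.append(
                {
                    "carrier": rec_id,
                    "backbone_pos": pos,
                    "start": pos + offset,
                    "end": pos + offset + ins["length"],
                    "length": ins["length"],
                    "seq": ins["seq"],
                }
            )
            pieces.append(ins["seq"])
            offset += ins["length"]
            prev = pos
        pieces.append(backbone[prev:])
        seqs[carrier] = SequenceRecord(rec_id, "".join(pieces), f"seed={seed}")
    truth = TruthRecord(
        kind="promoter_pair",
        seed=seed,
        data={"backbone_len": backbone_len, "regions": truth_regions},
    )
    return seqs["A"], seqs["Y"], truth


# ---------------------------------------------------------------------------
# Duplication + insertion scenario

DEFAULT_SPECIES_TREE = (
    "(fugu:95,(mekongensis:20,(luzonensis:6,(latipes:4,curvinotus:4):2):14):75);"
)


@dataclasses.dataclass
class ScenarioConfig:
    """Configuration of the duplication/insertion history to simulate.

    Ages in MY, rate in substitutions/site/MY.  ``seq_len`` is the number of
    neutral (third-codon-position) sites in the coding alignment;
    ``element_len`` the element length.  Defaults reflect the emulated
    history: duplication at 10 MY, element insertion at 8 MY, outermost
    calibration split at 95 MY; lengths are set so the +-2 SE dating
    interval can resolve the 2-MY gap (see the methods note).
    """

    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    outgroup: str = "fugu"
    dup_clade: tuple[str, ...] = ("luzonensis", "latipes", "curvinotus")
    host_taxon: str = "latipes"
    duplication_age: float = 10.0
    insertion_age: float = 8.0
    rate: float = 0.004
    kappa_ratio: float = 2.0
    seq_len: int = 24000
    element_len: int = 12000
    tir_len: int = 27
    tsd_len: int = 8
    n_copies: int = 8
    copy_divergence: float = 0.03
    backbone_len: int = 60000
    # extra indel regions besides the element itself (which plays region I)
    region_spec: tuple[tuple[str, int], ...] = (
        ("Y", 315), ("Y", 598), ("Y", 496), ("A", 728),
    )


@dataclasses.dataclass
class Scenario:
    """Simulated inputs ready for the full dating pipeline."""

    config: ScenarioConfig
    alignment: list[SequenceRecord]  # codon-embedded (positions 1,2 invariant)
    gene_tree_newick: str  # truth tree, branch lengths in MY
    element_consensus: SequenceRecord  # the true ancestral element
    element_copies: list[SequenceRecord]  # genomic copies for consensus building
    promoter_element: SequenceRecord  # the copy that inserted into the promoter
    truth: TruthRecord


class _N:  # minimal mutable tree node
    __slots__ = ("name", "age", "children", "seq")

    def __init__(self, name, age, children=None):
        self.name = name
        self.age = age
        self.children = children or []
        self.seq = None


def _parse_ultrametric(newick: str) -> _N:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    # ages from leaf depths (input assumed ultrametric with lengths in MY)
    def depth(node):
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d
    total = max(depth(lf) for lf in tree.leaf_node_iter())

    def convert(node):
        age = total - depth(node)
        name = node.taxon.label if node.taxon else None
        return _N(name, round(age, 10), [convert(c) for c in node.child_nodes()])

    return convert(tree.seed_node)


def _find_mrca(node: _N, labels: set[str]) -> Optional[_N]:
    def tips(n):
        if not n.children:
            return {n.name}
        return set().union(*(tips(c) for c in n.children))

    if not labels <= tips(node):
        return None
    best = node
    changed = True
    while changed:
        changed = False
        for c in best.children:
            if labels <= tips(c):
                best = c
                changed = True
                break
    return best


def _suffix_tips(node: _N, labels: set[str], suffix: str) -> _N:
    clone = _N(node.name + suffix if (node.name in labels) else node.name, node.age)
    clone.children = [_suffix_tips(c, labels, suffix) for c in node.children]
    return clone


def _to_newick(node: _N) -> str:
    def rec(n, parent_age):
        bl = parent_age - n.age
        if not n.children:
            return f"{n.name}:{bl:g}"
        inner = ",".join(rec(c, n.age) for c in n.children)
        return f"({inner}):{bl:g}"

    inner = ",".join(rec(c, node.age) for c in node.children)
    return f"({inner});"


def build_gene_tree(cfg: ScenarioConfig) -> _N:
    """Species tree with a gene duplication grafted onto the dup_clade stem:
    at ``duplication_age`` the lineage splits into paralog clades A and B
    that each mirror the species topology below."""
    root = _parse_ultrametric(cfg.species_tree)
    clade = set(cfg.dup_clade)
    crown = _find_mrca(root, clade)
    if crown is None:
        raise ValueError("dup_clade not monophyletic in species_tree")
    if not crown.age < cfg.duplication_age:
        raise ValueError("duplication_age must exceed the dup_clade crown age")
    if cfg.insertion_age > cfg.duplication_age:
        raise ValueError(
            "insertion_age exceeds the age of the paralog lineage it inserts into"
        )
    parent = None

    def find_parent(n):
        nonlocal parent
        for c in n.children:
            if c is crown:
                parent = n
            find_parent(c)

    find_parent(root)
    if parent is None or parent.age < cfg.duplication_age:
        raise ValueError("duplication_age older than the dup_clade stem")
    copy_a = _suffix_tips(crown, clade, "_A")
    copy_b = _suffix_tips(crown, clade, "_B")
    dup = _N("duplication", cfg.duplication_age, [copy_a, copy_b])
    parent.children = [dup if c is crown else c for c in parent.children]
    return root


def simulate_duplication_scenario(cfg: ScenarioConfig) -> Scenario:
    """Neutral sequences evolved along the duplicated gene tree, plus an
    element family whose promoter-borne copy inserted at ``insertion_age``."""
    rng = _rng(cfg.seed, "simulate_duplication_scenario")
    gene_tree = build_gene_tree(cfg)
    # evolve third-position sites down the tree
    gene_tree.seq = random_dna(rng, cfg.seq_len)

    def walk(node):
        for child in node.children:
            d = cfg.rate * (node.age - child.age)
            child.seq = evolve_sequence_k2p(node.seq, d, cfg.kappa_ratio, rng=rng)
            walk(child)

    walk(gene_tree)
    tips = {}

    def collect(node):
        if not node.children:
            tips[node.name] = node.seq
        for c in node.children:
            collect(c)

    collect(gene_tree)
    # embed as codons: positions 1 and 2 invariant across taxa
    pos12 = random_dna(rng, 2 * cfg.seq_len)
    alignment = []
    for name in sorted(tips):
        third = tips[name]
        codons = "".join(
            pos12[2 * i] + pos12[2 * i + 1] + third[i] for i in range(cfg.seq_len)
        )
        alignment.append(SequenceRecord(name, codons, "simulated coding alignment"))
    # element family
    consensus = make_tir_element(cfg.element_len, seed=cfg.seed, tir=random_dna(rng, cfg.tir_len))
    copies = [
        SequenceRecord(
            f"copy{k}",
            evolve_sequence_k2p(consensus, cfg.copy_divergence, cfg.kappa_ratio, rng=rng),
        )
        for k in range(cfg.n_copies)
    ]
    d_elem_true = cfg.rate * cfg.insertion_age
    promoter_element = SequenceRecord(
        "promoter_element",
        evolve_sequence_k2p(consensus, d_elem_true, cfg.kappa_ratio, rng=rng),
        f"inserted {cfg.insertion_age} MY ago",
    )
    ages = {}

    def record_ages(node):
        if node.children:
            key = node.name or "+".join(sorted(t for t in _tipset(node)))
            ages[key] = node.age
        for c in node.children:
            record_ages(c)

    def _tipset(node):
        if not node.children:
            return {node.name}
        return set().union(*(_tipset(c) for c in node.children))

    record_ages(gene_tree)
    truth = TruthRecord(
        kind="duplication_scenario",
        seed=cfg.seed,
        data={
            "duplication_age": cfg.duplication_age,
            "insertion_age": cfg.insertion_age,
            "rate": cfg.rate,
            "d_elem_true": d_elem_true,
            "node_ages": ages,
            "tips": sorted(tips),
        },
    )
    return Scenario(
        config=cfg,
        alignment=alignment,
        gene_tree_newick=_to_newick(gene_tree),
        element_consensus=SequenceRecord("element_consensus", consensus),
        element_copies=copies,
        promoter_element=promoter_element,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Motif planting


def plant_motif_instances(
    seq: SequenceRecord,
    consensus_site: str,
    n: int,
    seed: int = 0,
    strands: Optional[Sequence[str]] = None,
) -> tuple[SequenceRecord, TruthRecord]:
    """Overwrite *n* non-overlapping windows with the site (or its reverse
    complement on '-'); truth records positions and strands."""
    rng = _rng(seed, "plant_motif_instances")
    w = len(consensus_site)
    if w > len(seq.seq):
        raise ValueError("site longer than sequence")
    if strands is None:
        strands = ["+"] * n
    if len(strands) != n:
        raise ValueError("strands must have length n")
    if n == 0:
        return SequenceRecord(seq.id, seq.seq, seq.description), TruthRecord(
            "planted_motifs", seed, {"site": consensus_site, "instances": []}
        )
    for _ in range(200):
        positions = np.sort(rng.choice(np.arange(0, len(seq.seq) - w + 1), size=n, replace=False))
        if n == 1 or np.diff(positions).min() >= w:
            break
    else:
        raise RuntimeError("could not place motif instances without overlap")
    chars = list(seq.seq)
    instances = []
    for pos, strand in zip(positions, strands):
        site = consensus_site if strand == "+" else reverse_complement(consensus_site)
        chars[pos : pos + w] = site
        instances.append({"start": int(pos), "end": int(pos + w), "strand": strand})
    truth = TruthRecord("planted_motifs", seed, {"site": consensus_site, "instances": instances})
    return SequenceRecord(seq.id, "".join(chars), f"seed={seed}"), truth


# ---------------------------------------------------------------------------
# Full pipeline fixture


def scenario_to_pipeline_inputs(
    scenario: Scenario,
    out_dir,
    y_region_copies: tuple[int, ...] = (3, 1, 3),
) -> dict:
    """Materialize a scenario as the file set the CLI pipeline consumes.

    Builds the paralogous promoter pair — the evolved element inserted into
    the Y copy with a genuine target-site duplication as the TSS-proximal
    region, plus the configured extra indel regions — and a genome carrying
    the element family together with ``y_region_copies`` genomic copies of
    each Y-carried extra region (1 = single-copy sequence that classifies
    as a loss from the other paralog).  A-carried regions occur once, on
    the A promoter itself, which is part of the searchable genome.  Writes
    FASTA inputs plus the truth JSON and returns the path dictionary for
    :class:`tetracer.pipeline.PipelineConfig`.
    """
    import pathlib

    from .seq_core import write_fasta

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = scenario.config
    rng = _rng(cfg.seed, "scenario_to_pipeline_inputs")

    extra_spec = list(cfg.region_spec)
    n_y = sum(1 for c, _ in extra_spec if c == "Y")
    if len(y_region_copies) != n_y:
        raise ValueError("y_region_copies must match the Y entries of region_spec")
    prom_backbone = random_dna(rng, cfg.backbone_len)
    element_seq = scenario.promoter_element.seq
    k = cfg.tsd_len
    n_regions = len(extra_spec) + 1
    span = cfg.backbone_len // (n_regions + 1)
    positions = [span * (i + 1) for i in range(n_regions)]
    # the element takes the most TSS-proximal slot (promoters run 5'->3'
    # ending at the TSS, so the last position)
    elem_pos = positions[-1]
    inserts_y, inserts_a, y_regions = [], [], []
    for (carrier, length), pos in zip(extra_spec, positions[:-1]):
        seq = random_dna(rng, length)
        if carrier == "Y":
            inserts_y.append((pos, seq))
            y_regions.append(seq)
        else:
            inserts_a.append((pos, seq))
    # duplicate the target site: ...[T] element [T] rest, with T the k-mer at
    # the integration point (insert element+T right after the host's own T)
    tsd = prom_backbone[elem_pos : elem_pos + k]
    inserts_y.append((elem_pos + k, element_seq + tsd))

    def build(inserts):
        pieces = []
        prev = 0
        for pos, seq in sorted(inserts):
            pieces.append(prom_backbone[prev:pos])
            pieces.append(seq)
            prev = pos
        pieces.append(prom_backbone[prev:])
        return "".join(pieces)

    prom_y = SequenceRecord("promY", build(inserts_y), f"seed={cfg.seed}")
    prom_a = SequenceRecord("promA", build(inserts_a), f"seed={cfg.seed}")

    # genome: element family copies, then extra copies of repetitive regions
    genome_backbone = SequenceRecord("chrU", random_dna(rng, cfg.backbone_len))
    genome, _truth_copies = plant_element_copy_groups(
        genome_backbone,
        scenario.element_consensus.seq,
        [(cfg.n_copies, cfg.copy_divergence)],
        tsd_len=k,
        seed=cfg.seed,
    )
    tail_parts = [genome.seq]
    for seq, n_cop in zip(y_regions, y_region_copies):
        # one copy already sits on the Y promoter locus; plant n_cop - 1 more
        for c in range(max(0, n_cop - 1)):
            tail_parts.append(random_dna(rng, 400))
            tail_parts.append(evolve_sequence_k2p(seq, 0.01, rng=rng))
    tail_parts.append(random_dna(rng, 400))
    genome = SequenceRecord("chrU", "".join(tail_parts), f"seed={cfg.seed}")

    write_fasta([prom_a], out / "promoter_a.fasta")
    write_fasta([prom_y], out / "promoter_y.fasta")
    write_fasta([genome, prom_a, prom_y], out / "genome.fasta")
    write_fasta(scenario.alignment, out / "coding_alignment.fasta")
    (out / "truth.json").write_text(scenario.truth.to_json())
    return {
        "promoter_a": str(out / "promoter_a.fasta"),
        "promoter_y": str(out / "promoter_y.fasta"),
        "genome": str(out / "genome.fasta"),
        "coding_alignment": str(out / "coding_alignment.fasta"),
    }
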