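"""Kimura-2-parameter distances, neighbor joining, clock linearization, and
dating of a transposon insertion relative to a gene-duplication node.

The dating logic mirrors a classical molecular-clock workflow: pairwise K2P
distances on neutral (third codon position) sites, a neighbor-joining tree,
linearization by bottom-up tip-averaging of root-to-tip path lengths, and
conversion of substitution-per-site heights into absolute ages through a
single calibrated node (e.g. a 95-MY split).  The element insertion age is
``d / rate`` with the element-vs-consensus distance ``d`` accruing on a
single lineage (not ``2rt``: the consensus approximates the element at the
moment of insertion, so divergence accumulates on one branch only).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import dendropy
import numpy as np

from .seq_core import SequenceRecord

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_UNAMBIGUOUS = {"A", "C", "G", "T"}


class SaturationError(ValueError):
    """K2P distance undefined (log argument <= 0: sequences too diverged)."""


@dataclasses.dataclass
class PairwiseCounts:
    L: int  # compared (pairwise-complete) sites
    P: float  # transition proportion
    Q: float  # transversion proportion


@dataclasses.dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    se: np.ndarray

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for i, name in enumerate(self.taxa):
            row = " ".join(f"{x:.6f}" for x in self.d[i])
            lines.append(f"{name:<12s}{row}")
        return "\n".join(lines) + "\n"


def third_codon_positions(
    records: Sequence[SequenceRecord], frame_offset: int = 0
) -> list[SequenceRecord]:
    """Extract the third position of every codon from an aligned set."""
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    (aln_len,) = lengths
    usable = aln_len - frame_offset
    if usable % 3:
        warnings.warn(
            f"alignment length {aln_len} minus offset {frame_offset} not divisible by 3; "
            "trailing partial codon dropped"
        )
    return [
        SequenceRecord(r.id, r.seq[frame_offset + 2 :: 3], r.description) for r in records
    ]


def count_substitutions(a: str, b: str) -> PairwiseCounts:
    """Transition/transversion proportions with pairwise deletion of any
    column holding a gap or ambiguity code in either sequence."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    a, b = a.upper(), b.upper()
    L = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _UNAMBIGUOUS or y not in _UNAMBIGUOUS:
            continue
        L += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if L == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return PairwiseCounts(L=L, P=ts / L, Q=tv / L)


def k2p_distance(c: PairwiseCounts) -> tuple[float, float]:
    """Kimura-2-parameter distance and its analytic (delta-method) SE.

    d  = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
    se = sqrt((c1^2 P + c3^2 Q - (c1 P + c3 Q)^2) / L)
         with c1 = 1/(1-2P-Q), c2 = 1/(1-2Q), c3 = (c1+c2)/2.
    """
    P, Q, L = c.P, c.Q, c.L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated comparison (P={P:.4f}, Q={Q:.4f})")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    c1 = 1.0 / w1
    c2 = 1.0 / w2
    c3 = 0.5 * (c1 + c2)
    var = (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / L
    return d, math.sqrt(max(var, 0.0))


def k2p_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """All pairwise K2P distances (with SEs) of an aligned record set."""
    n = len(records)
    d = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist, s = k2p_distance(count_substitutions(records[i].seq, records[j].seq))
            d[i, j] = d[j, i] = dist
            se[i, j] = se[j, i] = s
    return DistanceMatrix([r.id for r in records], d, se)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Deterministic tie-breaking (smallest active-node index pair); negative
    branch lengths are clamped to zero with the deficit transferred to the
    sibling branch of the same join.  Returns an unrooted tree (trifurcating
    seed node).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for name in dm.taxa:
        leaf = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(leaf)
    active = list(range(n))
    D = dm.d.astype(float).copy()
    next_index = n
    store: dict[int, dendropy.Node] = {i: nodes[i] for i in range(n)}
    # D grows as new internal nodes are appended
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * D[i, j] - r[i] - r[j]
                key = (qv, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(store[i])
        store[i].edge.length = li
        parent.add_child(store[j])
        store[j].edge.length = lj
        # distances from the new node
        newD = np.zeros((D.shape[0] + 1, D.shape[1] + 1))
        newD[: D.shape[0], : D.shape[1]] = D
        for k in active:
            if k in (i, j):
                continue
            newD[next_index, k] = newD[k, next_index] = 0.5 * (
                D[i, k] + D[j, k] - D[i, j]
            )
        D = newD
        store[next_index] = parent
        active = [k for k in active if k not in (i, j)] + [next_index]
        next_index += 1
    # final three nodes joined at the seed (unrooted trifurcation)
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    lens = [li, lj, lk]
    order = [i, j, k]
    for idx in range(3):
        if lens[idx] < 0:
            # transfer the deficit to the longest adjacent pendant
            other = max((o for o in range(3) if o != idx), key=lambda o: lens[o])
            lens[other] += lens[idx]
            lens[idx] = 0.0
    seed = tree.seed_node
    for node_idx, length in zip(order, lens):
        seed.add_child(store[node_idx])
        store[node_idx].edge.length = length
    tree.is_rooted = False
    return tree


def tree_path_length(tree: dendropy.Tree, a: str, b: str) -> float:
    """Patristic distance between two leaf labels."""
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    return pdm.patristic_distance(tns.get_taxon(a), tns.get_taxon(b))


# ---------------------------------------------------------------------------
# Clock linearization and calibration


@dataclasses.dataclass
class ClockTree:
    """Rooted ultrametric tree with node ages in MY.

    ``rate`` is the substitution rate per site per MY implied by the
    calibration node; tips are at age 0 and every node carries ``node.age``.
    """

    tree: dendropy.Tree
    rate: float
    calibration_labels: list[str]
    calibration_age: float

    def mrca(self, labels: Sequence[str]) -> dendropy.Node:
        taxa = [self.tree.taxon_namespace.get_taxon(l) for l in labels]
        if any(t is None for t in taxa):
            missing = [l for l, t in zip(labels, taxa) if t is None]
            raise KeyError(f"unknown taxa: {missing}")
        return self.tree.mrca(taxa=taxa)

    def age_of(self, labels: Sequence[str]) -> float:
        return self.mrca(labels).age

    def root_age(self) -> float:
        return self.tree.seed_node.age

    def as_newick(self) -> str:
        """Newick with node ages as comments."""
        t = self.tree.clone(depth=1)
        for nd in t:
            if not nd.is_leaf():
                nd.label = f"age={nd.age:.4f}"
        return t.as_string(schema="newick", suppress_rooting=True)


def _mean_tip_height(node: dendropy.Node) -> tuple[float, int]:
    """Tip-count-weighted mean path length from *node* down to its tips."""
    if node.is_leaf():
        return 0.0, 1
    total = 0.0
    count = 0
    for child in node.child_nodes():
        h, c = _mean_tip_height(child)
        total += c * (h + (child.edge.length or 0.0))
        count += c
    return total / count, count


def linearize_and_calibrate(
    tree: dendropy.Tree,
    outgroup: str,
    calibration_labels: Sequence[str],
    calibration_age: float,
) -> ClockTree:
    """Root on the outgroup edge, impose a clock, and convert to ages.

    Node heights are re-estimated bottom-up: each internal node's height is
    the tip-count-weighted mean of its root-to-tip path lengths.  The root
    is placed on the outgroup edge at the point balancing the outgroup tip
    against the mean ingroup tip depth (clipped to the edge).  Heights are
    made monotone (child <= parent) and scaled so that the MRCA of
    ``calibration_labels`` sits at ``calibration_age``; the implied rate is
    ``calibration height (subs/site) / calibration_age``.
    """
    tree = tree.clone(depth=1)
    tns = tree.taxon_namespace
    og_taxon = tns.get_taxon(outgroup)
    if og_taxon is None:
        raise KeyError(f"outgroup {outgroup!r} not in tree")
    og_leaf = tree.find_node_with_taxon_label(outgroup)
    tree.is_rooted = True
    # root on the outgroup pendant edge (explicit split keeps lengths intact)
    e = og_leaf.edge.length or 0.0
    tree.reroot_at_edge(
        og_leaf.edge, length1=e / 2.0, length2=e / 2.0, update_bipartitions=False
    )
    root = tree.seed_node
    ingroup = [c for c in root.child_nodes() if c is not og_leaf][0]
    h_in, _ = _mean_tip_height(ingroup)
    # place the root on the outgroup-tip-to-ingroup-node path at the point
    # balancing the outgroup tip against the mean ingroup tip depth
    total = (og_leaf.edge.length or 0.0) + (ingroup.edge.length or 0.0)
    y = min(max((total - h_in) / 2.0, 0.0), total)  # root -> ingroup node
    og_leaf.edge.length = total - y
    ingroup.edge.length = y
    # bottom-up heights
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd._height = 0.0
        else:
            nd._height = _mean_tip_height(nd)[0]
    # enforce monotonicity top-down
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd._height > nd.parent_node._height:
            nd._height = nd.parent_node._height
    calib = tree.mrca(taxa=[tns.get_taxon(l) for l in calibration_labels])
    h_cal = calib._height
    if h_cal <= 0:
        raise ValueError("degenerate calibration: zero height at calibration node")
    rate = h_cal / calibration_age
    for nd in tree.preorder_node_iter():
        nd.age = nd._height / rate
    # rewrite branch lengths in MY so the tree is ultrametric
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age - nd.age
    return ClockTree(
        tree=tree,
        rate=rate,
        calibration_labels=list(calibration_labels),
        calibration_age=calibration_age,
    )


# ---------------------------------------------------------------------------
# Insertion dating


@dataclasses.dataclass
class InsertionDating:
    d_elem: float
    se_elem: float
    age_point: float
    age_low: float
    age_high: float
    branch_placement: str
    verdict_vs_reference: str
    reference_age: float


def date_insertion(
    d_elem: float,
    se_elem: float,
    clock: ClockTree,
    host_lineage: str,
    reference_labels: Sequence[str],
    z: float = 2.0,
) -> InsertionDating:
    """Date an element insertion and order it against a reference node.

    The insertion age is ``d_elem / rate`` (single-lineage divergence since
    the element copy separated from the family consensus), with a
    ``+- z * se`` interval.  The verdict is *younger* if the whole interval
    lies below the reference node's age, *older* if entirely above, else
    *indistinguishable*.
    """
    rate = clock.rate
    if rate <= 0:
        raise ValueError("clock rate must be positive")
    age_point = d_elem / rate
    age_low = max(0.0, (d_elem - z * se_elem) / rate)
    age_high = max(0.0, (d_elem + z * se_elem) / rate)
    # branch placement along the host lineage
    node = clock.tree.find_node_with_taxon_label(host_lineage)
    if node is None:
        raise KeyError(f"host lineage {host_lineage!r} not in tree")
    placement = None
    child = node
    while child.parent_node is not None:
        parent = child.parent_node
        if child.age <= age_point <= parent.age:
            tips = sorted(lf.taxon.label for lf in child.leaf_iter())
            placement = (
                f"branch above clade {{{','.join(tips)}}} "
                f"(ages {child.age:.3f}-{parent.age:.3f} MY)"
            )
            break
        child = parent
    if placement is None:
        placement = f"older than the root ({clock.root_age():.3f} MY)"
    ref_age = clock.age_of(reference_labels)
    if age_high < ref_age:
        verdict = "younger"
    elif age_low > ref_age:
        verdict = "older"
    else:
        verdict = "indistinguishable"
    return InsertionDating(
        d_elem=d_elem,
        se_elem=se_elem,
        age_point=age_point,
        age_low=age_low,
        age_high=age_high,
        branch_placement=placement,
        verdict_vs_reference=verdict,
        reference_age=ref_age,
    )
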