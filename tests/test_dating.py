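import math

import dendropy
import numpy as np
import pytest

from tetracer.dating import (
    DistanceMatrix,
    PairwiseCounts,
    SaturationError,
    count_substitutions,
    date_insertion,
    k2p_distance,
    k2p_matrix,
    linearize_and_calibrate,
    nj_tree,
    third_codon_positions,
    tree_path_length,
)
from tetracer.seq_core import SequenceRecord
from tetracer.simulate import (
    ScenarioConfig,
    _rng,
    evolve_sequence_k2p,
    k2p_proportions,
    random_dna,
    simulate_duplication_scenario,
)
from tetracer.annotation import build_consensus


class TestThirdCodonPositions:
    def test_extracts_every_third_base(self):
        recs = [SequenceRecord("a", "ATGAAATTT")]
        assert third_codon_positions(recs)[0].seq == "GAT"

    def test_single_codon(self):
        assert third_codon_positions([SequenceRecord("a", "ATG")])[0].seq == "G"

    def test_concatenation_property(self):
        x, y = "ATGAAA", "TTTCCC"
        a = third_codon_positions([SequenceRecord("a", x + y)])[0].seq
        b = (
            third_codon_positions([SequenceRecord("a", x)])[0].seq
            + third_codon_positions([SequenceRecord("a", y)])[0].seq
        )
        assert a == b

    def test_partial_codon_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            rec = third_codon_positions([SequenceRecord("a", "ATGAAAT")])[0]
        assert rec.seq == "GA"

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            third_codon_positions([SequenceRecord("a", "ATG"), SequenceRecord("b", "ATGATG")])


class TestCountSubstitutions:
    def test_identical(self):
        c = count_substitutions("AAAA", "AAAA")
        assert (c.P, c.Q, c.L) == (0.0, 0.0, 4)

    def test_single_transition(self):
        c = count_substitutions("AAAA", "GAAA")
        assert c.P == 0.25 and c.Q == 0.0

    def test_gap_and_ambiguity_columns_excluded(self):
        c = count_substitutions("AC-G", "ATTG")
        assert c.L == 3 and c.P == pytest.approx(1 / 3) and c.Q == 0.0
        c = count_substitutions("ACNG", "ATAG")
        assert c.L == 3

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            count_substitutions("--", "AC")


class TestK2PDistance:
    def test_zero_divergence(self):
        assert k2p_distance(PairwiseCounts(100, 0.0, 0.0)) == (0.0, 0.0)

    def test_formula_arithmetic(self):
        d, _ = k2p_distance(PairwiseCounts(10**9, 0.1, 0.05))
        assert d == pytest.approx(-0.5 * math.log(0.75) - 0.25 * math.log(0.9))

    def test_analytic_se_reproduces_reported_values(self):
        # 1316 sites at d=0.034 -> se 0.005; 1024 sites at d=0.010 -> 0.003
        for L, d_true, se_expected in [(1316, 0.034, 0.005), (1024, 0.010, 0.003)]:
            P, Q = k2p_proportions(d_true, 2.0)
            d, se = k2p_distance(PairwiseCounts(L, P, Q))
            assert d == pytest.approx(d_true, abs=1e-9)
            assert round(se, 3) == se_expected

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance(PairwiseCounts(100, 0.5, 0.1))

    def test_small_d_approaches_p_plus_q(self):
        P, Q = 1e-4, 5e-5
        d, _ = k2p_distance(PairwiseCounts(10**6, P, Q))
        assert d == pytest.approx(P + Q, rel=1e-3)

    def test_monotone_in_p_and_q(self):
        base, _ = k2p_distance(PairwiseCounts(100, 0.05, 0.05))
        up_p, _ = k2p_distance(PairwiseCounts(100, 0.06, 0.05))
        up_q, _ = k2p_distance(PairwiseCounts(100, 0.05, 0.06))
        assert up_p > base and up_q > base

    def test_empirical_sd_matches_analytic_se(self):
        # estimator spread over simulated pairs vs the delta-method SE
        L, d_true = 2000, 0.05
        rng = _rng(77, "sd-check")
        anc = random_dna(rng, L)
        ests = []
        for _ in range(400):
            mut = evolve_sequence_k2p(anc, d_true, rng=rng)
            ests.append(k2p_distance(count_substitutions(anc, mut))[0])
        P, Q = k2p_proportions(d_true, 2.0)
        _, se = k2p_distance(PairwiseCounts(L, P, Q))
        assert np.std(ests, ddof=1) == pytest.approx(se, rel=0.10)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["t1", "t2", "t3"],
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
            np.zeros((3, 3)),
        )
        tree = nj_tree(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["t1"] == pytest.approx(0.05)
        assert lengths["t2"] == pytest.approx(0.15)
        assert lengths["t3"] == pytest.approx(0.25)

    def test_additive_matrix_reproduced_exactly(self):
        taxa = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 3, 7, 9], [3, 0, 8, 10], [7, 8, 0, 6], [9, 10, 6, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(taxa, d, np.zeros((4, 4))))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i < j:
                    assert tree_path_length(tree, x, y) == pytest.approx(d[i, j])

    def test_ultrametric_matrix_reproduced(self):
        taxa = ["a", "b", "c", "d", "e"]
        # ultrametric: ((a,b):1,(c,d):0.5,e) depths 2,2,2
        d = np.array(
            [
                [0, 2, 4, 4, 6],
                [2, 0, 4, 4, 6],
                [4, 4, 0, 1, 6],
                [4, 4, 1, 0, 6],
                [6, 6, 6, 6, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(taxa, d, np.zeros((5, 5))))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i < j:
                    assert tree_path_length(tree, x, y) == pytest.approx(d[i, j])

    def test_matches_independent_nj_topology(self):
        # scikit-bio's NJ as an independent cross-check on a noisy matrix
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(6)]
        base = np.array(
            [
                [0, 2, 4, 4, 6, 6],
                [2, 0, 4, 4, 6, 6],
                [4, 4, 0, 2, 6, 6],
                [4, 4, 2, 0, 6, 6],
                [6, 6, 6, 6, 0, 2],
                [6, 6, 6, 6, 2, 0],
            ],
            dtype=float,
        )
        noise = rng.normal(0, 0.05, base.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d = base + noise
        mine = nj_tree(DistanceMatrix(taxa, d, np.zeros_like(d)))
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        theirs = sk_nj(SkDM(d, ids=taxa))
        tns = dendropy.TaxonNamespace(taxa)
        t1 = dendropy.Tree.get(data=mine.as_string(schema="newick"), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=str(theirs.root_at(theirs.find("t0").parent)),
                               schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        b1 = {b.split_bitmask for b in t1.bipartition_encoding if not b.is_trivial()}
        b2 = {b.split_bitmask for b in t2.bipartition_encoding if not b.is_trivial()}
        assert b1 == b2

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)), np.zeros((2, 2))))


def _ultrametric_tree():
    newick = "(((a:1,b:1):1,c:2):3,d:5);"
    return dendropy.Tree.get(data=newick, schema="newick")


class TestLinearizeAndCalibrate:
    def test_already_ultrametric_heights_preserved(self):
        clock = linearize_and_calibrate(_ultrametric_tree(), "d", ["a", "d"], 5.0)
        assert clock.rate == pytest.approx(1.0)
        assert clock.age_of(["a", "b"]) == pytest.approx(1.0)
        assert clock.age_of(["a", "c"]) == pytest.approx(2.0)
        assert clock.root_age() == pytest.approx(5.0)

    def test_two_sided_midpoint_for_two_tip_case(self):
        tree = dendropy.Tree.get(data="(a:0.3,(b:0.05,c:0.05):0.05);", schema="newick")
        clock = linearize_and_calibrate(tree, "a", ["a", "b"], 10.0)
        # balance point: root-to-a == root-to-mean-{b,c} == (0.35 + 0.05)/2
        assert clock.root_age() == pytest.approx(10.0)
        assert clock.rate == pytest.approx(0.2 / 10.0)

    def test_output_is_ultrametric(self):
        cfg = ScenarioConfig(seed=6, seq_len=2000, element_len=2000)
        sc = simulate_duplication_scenario(cfg)
        dm = k2p_matrix(third_codon_positions(sc.alignment))
        clock = linearize_and_calibrate(nj_tree(dm), "fugu", ["fugu", "latipes_A"], 95.0)
        depths = []

        def tip_depth(node):
            d = 0.0
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            return d

        for lf in clock.tree.leaf_node_iter():
            depths.append(tip_depth(lf))
        assert max(depths) - min(depths) <= 1e-9 * max(depths)

    def test_node_age_recovery_on_clock_simulation(self):
        # estimated linearized ages within 3 simulation SEs of the truth
        cfg = ScenarioConfig(seed=6)
        sc = simulate_duplication_scenario(cfg)
        dm = k2p_matrix(third_codon_positions(sc.alignment))
        clock = linearize_and_calibrate(nj_tree(dm), "fugu", ["fugu", "latipes_A"], 95.0)
        checks = [
            (["latipes_A", "curvinotus_A"], 4.0),
            (["latipes_A", "luzonensis_A"], 6.0),
            (["latipes_A", "latipes_B"], 10.0),
            (["mekongensis", "latipes_A"], 20.0),
        ]
        for labels, true_age in checks:
            est = clock.age_of(labels)
            h = true_age * cfg.rate
            se_h = math.sqrt(h / cfg.seq_len)  # binomial-order noise bound
            assert abs(est - true_age) <= 3 * max(se_h / cfg.rate, 0.5)

    def test_degenerate_calibration_raises(self):
        tree = dendropy.Tree.get(data="(a:0.1,(b:0.0,c:0.0):0.1);", schema="newick")
        with pytest.raises(ValueError):
            linearize_and_calibrate(tree, "a", ["b", "c"], 10.0)


class TestDateInsertion:
    def _clock(self):
        return linearize_and_calibrate(_ultrametric_tree(), "d", ["a", "d"], 50.0)

    def test_zero_distance_is_age_zero_younger_than_everything(self):
        clock = self._clock()
        res = date_insertion(0.0, 0.0, clock, "a", ["a", "b"])
        assert res.age_point == 0.0
        assert res.verdict_vs_reference == "younger"
        assert "branch above clade {a}" in res.branch_placement

    def test_age_arithmetic(self):
        clock = self._clock()
        # rate = 5 subs-units / 50 MY = 0.1; d=0.034 at rate 0.004 -> 8.5 MY
        res = date_insertion(0.034, 0.0, clock, "a", ["a", "c"])
        assert res.age_point == pytest.approx(0.034 / clock.rate)
        assert 0.034 / 0.004 == pytest.approx(8.5)

    def test_verdict_flips_with_interval_position(self):
        clock = self._clock()  # rate 0.1/MY; ages: (a,b)=10, (a,c)=20, root=50
        young = date_insertion(0.5, 0.1, clock, "a", ["a", "c"], z=2)
        assert young.age_high == pytest.approx(7.0)
        assert young.verdict_vs_reference == "younger"
        old = date_insertion(2.5, 0.1, clock, "a", ["a", "c"], z=2)
        assert old.verdict_vs_reference == "older"
        mid = date_insertion(2.0, 0.1, clock, "a", ["a", "c"], z=2)
        assert mid.verdict_vs_reference == "indistinguishable"

    def test_ordering_invariant_under_calibration_rescaling(self):
        tree1 = _ultrametric_tree()
        tree2 = _ultrametric_tree()
        c1 = linearize_and_calibrate(tree1, "d", ["a", "d"], 50.0)
        c2 = linearize_and_calibrate(tree2, "d", ["a", "d"], 100.0)
        for d_elem in (0.5, 2.0, 2.5):
            r1 = date_insertion(d_elem, 0.01, c1, "a", ["a", "c"])
            r2 = date_insertion(d_elem, 0.01, c2, "a", ["a", "c"])
            assert r1.verdict_vs_reference == r2.verdict_vs_reference
            assert r2.age_point == pytest.approx(2 * r1.age_point)

    def test_full_scenario_recovers_younger_insertion(self):
        cfg = ScenarioConfig(seed=7)
        sc = simulate_duplication_scenario(cfg)
        dm = k2p_matrix(third_codon_positions(sc.alignment))
        clock = linearize_and_calibrate(nj_tree(dm), "fugu", ["fugu", "latipes_A"], 95.0)
        cons = build_consensus([c.seq for c in sc.element_copies], 0.5)
        d, se = k2p_distance(count_substitutions(cons.consensus, sc.promoter_element.seq))
        res = date_insertion(d, se, clock, "latipes_B", ["latipes_A", "latipes_B"])
        assert res.verdict_vs_reference == "younger"
        assert res.age_low <= cfg.insertion_age <= res.age_high
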