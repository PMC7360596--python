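"""Neighbor-joining, rooting and tree queries."""

import itertools

import numpy as np
import pytest

from supergene.distances import DistanceMatrix, pairwise_matrix
from supergene.phylogeny import PhyloTree, build_nj_tree
from supergene.simulate import SimulationConfig, simulate_haplotypes


def _matrix_from_tree(newick, labels):
    t = PhyloTree.from_newick(newick)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = t.tip_distance(labels[i], labels[j])
    return DistanceMatrix(labels, d, np.ones((n, n), dtype=int))


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        labels = ["A", "B", "C", "D"]
        dm = _matrix_from_tree(
            "((A:0.01,B:0.02):0.03,C:0.04,D:0.05);", labels)
        tree = build_nj_tree(dm)
        for i, j in itertools.combinations(range(4), 2):
            got = tree.tip_distance(labels[i], labels[j])
            assert got == pytest.approx(dm.d[i, j], abs=1e-12)
        # topology: A and B are cherries
        rooted = tree.root_with_outgroup(["D"])
        assert rooted.is_monophyletic({"A", "B"})

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        dm = DistanceMatrix(["x", "y", "z"], d, np.ones((3, 3)))
        tree = build_nj_tree(dm)
        # pendant lengths (d_xy + d_xz - d_yz)/2 etc.
        assert tree.tip_distance("x", "y") == pytest.approx(0.3)
        assert tree.tip_distance("x", "z") == pytest.approx(0.5)
        assert tree.tip_distance("y", "z") == pytest.approx(0.6)

    def test_tip_permutation_invariance(self, rng):
        labels = list("ABCDEFGH")
        nwk = ("(((A:0.011,B:0.007):0.004,(C:0.009,D:0.013):0.006):0.008,"
               "((E:0.012,F:0.005):0.007,G:0.014):0.003,H:0.02);")
        dm = _matrix_from_tree(nwk, labels)
        perm = list(rng.permutation(labels))
        dm_p = dm.subset(perm)
        t1, t2 = build_nj_tree(dm), build_nj_tree(dm_p)
        for a, b in itertools.combinations(labels, 2):
            assert t1.tip_distance(a, b) == pytest.approx(
                t2.tip_distance(a, b), abs=1e-12)

    def test_matches_independent_nj_implementation(self):
        # cross-check against scikit-bio's neighbor joining
        import skbio

        labels = list("ABCDEF")
        nwk = ("((A:0.01,B:0.02):0.015,(C:0.012,D:0.008):0.011,"
               "(E:0.02,F:0.03):0.005);")
        dm = _matrix_from_tree(nwk, labels)
        mine = build_nj_tree(dm)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=labels))
        for a, b in itertools.combinations(labels, 2):
            assert mine.tip_distance(a, b) == pytest.approx(
                float(sk.find(a).distance(sk.find(b))), abs=1e-10)

    def test_undefined_entries_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            build_nj_tree(DistanceMatrix(list("xyz"), d, np.ones((3, 3))))

    def test_topology_recovery_under_simulation(self):
        # the Sb clade must come out monophyletic on NJ trees built from
        # simulated alignments at the default sequence scale
        ok = 0
        reps = 25
        for seed in range(reps):
            cfg = SimulationConfig(
                group_sizes={"outgroup": 1, "invicta_SB": 3,
                             "richteri_SB": 3, "Sb": 3},
                seq_length=100_000, n_blocks=1, seed=1000 + seed)
            blocks, truth = simulate_haplotypes(cfg)
            dm = pairwise_matrix(blocks)
            rooted = build_nj_tree(dm).root_with_outgroup(["outgroup_1"])
            sb = [l for l, g in truth.groups.items() if g == "Sb"]
            ric_sb = [l for l, g in truth.groups.items()
                      if g in ("richteri_SB", "Sb")]
            if rooted.is_monophyletic(sb) and rooted.is_monophyletic(ric_sb):
                ok += 1
        assert ok >= 0.9 * reps


class TestRooting:
    NWK = "((A:1.0,B:1.5):0.5,(C:0.8,D:0.7):0.6,OG:9.0);"

    def test_rerooting_preserves_tip_to_tip_paths(self):
        t = PhyloTree.from_newick(self.NWK, rooted=False)
        rooted = t.root_with_outgroup(["OG"])
        for a, b in itertools.combinations(["A", "B", "C", "D", "OG"], 2):
            assert rooted.tip_distance(a, b) == pytest.approx(
                t.tip_distance(a, b), abs=1e-12)

    def test_root_splits_outgroup_from_ingroup(self):
        rooted = PhyloTree.from_newick(self.NWK, rooted=False) \
            .root_with_outgroup(["OG"])
        assert rooted.is_monophyletic({"A", "B", "C", "D"})

    def test_balanced_placement_recovers_clock_root_depth(self):
        # ultrametric tree, every tip at depth 10 from the true root
        nwk = "((A:2.0,B:2.0):8.0,OG:10.0);"
        t = PhyloTree.from_newick(nwk, rooted=False)
        rooted = t.root_with_outgroup(["OG"])
        root = rooted.mrca(["A", "OG"])
        assert rooted.path_length(root, "A") == pytest.approx(10.0)
        assert rooted.path_length(root, "OG") == pytest.approx(10.0)

    def test_non_clade_outgroup_rejected(self):
        t = PhyloTree.from_newick(self.NWK, rooted=False)
        with pytest.raises(ValueError, match="clade"):
            t.root_with_outgroup(["A", "C"])

    def test_simulated_ingroup_root_separates_invicta(self, small_sim):
        blocks, truth = small_sim
        dm = pairwise_matrix(blocks)
        rooted = build_nj_tree(dm).root_with_outgroup(["outgroup_1"])
        rest = [l for l, g in truth.groups.items()
                if g in ("richteri_SB", "Sb")]
        assert rooted.is_monophyletic(rest)


@pytest.fixture(scope="module")
def tree():
    return PhyloTree.from_newick(
        "(((A:0.001,B:0.002):0.004,C:0.01):0.02,D:0.05);")


class TestQueries:

    def test_mrca_single_tip_is_itself(self, tree):
        assert tree.mrca(["A"]).taxon.label == "A"

    def test_mrca_all_tips_is_root(self, tree):
        node = tree.mrca(["A", "B", "C", "D"])
        assert node.parent_node is None

    def test_unknown_tip_raises(self, tree):
        with pytest.raises(KeyError):
            tree.mrca(["A", "nope"])

    def test_path_lengths(self, tree):
        ab = tree.mrca(["A", "B"])
        assert tree.path_length(ab, "A") == pytest.approx(0.001)
        abc = tree.mrca(["A", "C"])
        assert tree.path_length(abc, "A") == pytest.approx(0.005)
        assert tree.path_length(ab, "A") == 0.001
        # node == tip -> zero
        assert tree.path_length(tree.mrca(["A"]), "A") == 0.0

    def test_non_ancestor_raises(self, tree):
        ab = tree.mrca(["A", "B"])
        with pytest.raises(ValueError):
            tree.path_length(ab, "C")

    def test_monophyly(self, tree):
        assert tree.is_monophyletic({"A", "B"})
        assert not tree.is_monophyletic({"B", "C"})  # complement of a clade
        assert tree.is_monophyletic({"D"})

    def test_path_equals_matrix_on_additive_tree(self, tree):
        # patristic distances from the tree equal mrca-decomposed sums
        for a, b in itertools.combinations(["A", "B", "C", "D"], 2):
            m = tree.mrca([a, b])
            assert tree.tip_distance(a, b) == pytest.approx(
                tree.path_length(m, a) + tree.path_length(m, b))

    def test_newick_roundtrip(self, tree, tmp_path):
        tree.write_newick(tmp_path / "t.nwk")
        back = PhyloTree.read_newick(tmp_path / "t.nwk")
        assert sorted(back.tip_labels) == ["A", "B", "C", "D"]
        assert back.tip_distance("A", "D") == pytest.approx(
            tree.tip_distance("A", "D"))
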