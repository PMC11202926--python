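import dendropy
import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix, UndefinedDistanceError, distance_matrix
from barcodekit.phylogeny import bootstrap_support, monophyly_check, nj, tree_to_newick


def path_lengths(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(taxa)
    return {
        (a, b): pdm.distance(taxa[a], taxa[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }


def random_additive_matrix(n, seed):
    """Distances realised on a random binary tree with random branch lengths."""
    rng = np.random.default_rng(seed)
    import random as pyrandom

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=n, rng=pyrandom.Random(seed),
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.05, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in taxa]
    d = np.array(
        [
            [0.0 if a == b else pdm.distance(taxa.get_taxon(a), taxa.get_taxon(b)) for b in labels]
            for a in labels
        ]
    )
    return DistanceMatrix(labels, d)


class TestNJ:
    def test_four_taxon_additive_example(self):
        ids = list("ABCD")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        m = DistanceMatrix(ids, d)
        tree = nj(m)
        # AB|CD split present and all path lengths reproduced exactly
        assert monophyly_check(tree, {"A": "x", "B": "x", "C": "y", "D": "y"}) == {
            "x": True,
            "y": True,
        }
        paths = path_lengths(tree)
        for (a, b), got in paths.items():
            assert got == pytest.approx(m.pair(a, b), abs=1e-12)

    def test_three_taxon_closed_form(self):
        m = DistanceMatrix(list("ABC"), np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = nj(m)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (12, 2)])
    def test_exact_on_random_additive_matrices(self, n, seed):
        m = random_additive_matrix(n, seed)
        paths = path_lengths(nj(m))
        for (a, b), got in paths.items():
            assert got == pytest.approx(m.pair(a, b), abs=1e-9)

    def test_topology_agrees_with_independent_implementation(self):
        skbio = pytest.importorskip("skbio")

        def nontrivial_bipartitions(tree):
            leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            out = set()
            for node in tree.preorder_node_iter():
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if 1 < len(side) < len(leaves) - 1:
                    out.add(min(side, leaves - side, key=sorted))
            return out

        for seed in range(3):
            m = random_additive_matrix(9, seed + 10)
            mine = nontrivial_bipartitions(nj(m))
            other_newick = str(skbio.tree.nj(skbio.DistanceMatrix(m.d, m.ids)))
            other = nontrivial_bipartitions(
                dendropy.Tree.get(data=other_newick, schema="newick")
            )
            assert mine == other

    def test_undefined_entries_rejected_with_pair_list(self):
        d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        with pytest.raises(UndefinedDistanceError, match="a.*c"):
            nj(DistanceMatrix(["a", "b", "c"], d))

    def test_negative_branches_clamped(self):
        # a non-additive matrix known to produce a negative NJ estimate
        d = np.array(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 0.1], [4, 4, 0.1, 0]], float
        )
        tree = nj(DistanceMatrix(list("ABCD"), d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0


class TestBootstrap:
    def test_two_clusters_get_high_central_support(self, small_sim):
        # one species pair from each of two genera keeps this quick
        records = [r for r in small_sim.records if r.morphological_label in ("Gena spa", "Genb spb")]
        tree = bootstrap_support(records, B=100, seed=5)
        species = {r.specimen_id: r.morphological_label for r in records}
        assert all(monophyly_check(tree, species).values())
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        ]
        assert max(supports) >= 95.0

    def test_single_replicate_supports_are_all_or_nothing(self, small_sim):
        records = small_sim.records[:6]
        tree = bootstrap_support(records, B=1, seed=2)
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.label is not None:
                assert float(node.label) in (0.0, 100.0)

    def test_reproducible_bit_exact_under_fixed_seed(self, small_sim):
        records = small_sim.records[:8]
        a = tree_to_newick(bootstrap_support(records, B=25, seed=7))
        b = tree_to_newick(bootstrap_support(records, B=25, seed=7))
        assert a == b

    def test_column_permutation_leaves_topology_unchanged(self, small_sim):
        from barcodekit.seqio import BarcodeRecord

        records = small_sim.records[:8]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(records[0].sequence))
        shuffled = [
            BarcodeRecord(r.specimen_id, "".join(r.sequence[i] for i in perm))
            for r in records
        ]
        t1 = nj(distance_matrix(records))
        t2 = nj(distance_matrix(shuffled))
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_invalid_replicate_count_rejected(self, small_sim):
        with pytest.raises(ValueError):
            bootstrap_support(small_sim.records[:4], B=0, seed=0)


class TestMonophyly:
    def test_intruder_breaks_monophyly(self):
        newick = "((a1:1,(a2:1,b1:1):1):1,(b2:1,b3:1):1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
        result = monophyly_check(tree, labels)
        assert result["A"] is False and result["B"] is False

    def test_singletons_are_monophyletic_by_convention(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1);", schema="newick")
        labels = {"a": "W", "b": "X", "c": "Y", "d": "Z"}
        assert all(monophyly_check(tree, labels).values())
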