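from __future__ import annotations

import random

import numpy as np
import pytest

from coibarcode import (
    BarcodeError,
    SimulationConfig,
    assess_monophyly,
    bootstrap_support,
    from_newick,
    nj_build,
    simulate,
    to_newick,
)
from coibarcode.divergence import DistanceMatrix

from _oracles import TopologyBank, bipartitions_of_edges, random_additive_matrix


def matrix_from_array(ids, arr):
    n = len(ids)
    return DistanceMatrix(list(ids), np.asarray(arr, dtype=float),
                          np.full((n, n), 655, dtype=int),
                          np.ones((n, n), dtype=bool))


def named_bipartitions(tree):
    return set(tree.bipartitions())


class TestNJBuild:
    def test_four_leaf_additive_example(self):
        # true tree ((A:1,B:2):1,(C:3,D:4)); NJ must recover split AB|CD,
        # internal branch 1 and pendant branches 1,2,3,4
        ids = ["A", "B", "C", "D"]
        D = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = nj_build(matrix_from_array(ids, D))
        bip = tree.bipartitions()
        [(side, node)] = list(bip.items())
        assert side in ({"A", "B"}, {"C", "D"})
        assert node.length == pytest.approx(1.0)
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_leaf_closed_form(self):
        tree = nj_build(matrix_from_array(
            ["A", "B", "C"], [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 1, "C": 3})

    def test_zero_distance_pair_becomes_siblings(self):
        ids = ["a1", "a2", "b1", "b2"]
        D = [[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 0], [4, 4, 0, 0]]
        tree = nj_build(matrix_from_array(ids, D))
        assert named_bipartitions(tree) == {frozenset({"b1", "b2"})}

    def test_fewer_than_three_leaves_is_error(self):
        with pytest.raises(BarcodeError):
            nj_build(matrix_from_array(["A", "B"], [[0, 1], [1, 0]]))

    def test_undefined_entry_is_error_naming_pair(self):
        m = matrix_from_array(["A", "B", "C"],
                              [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        m.defined[0, 1] = m.defined[1, 0] = False
        with pytest.raises(BarcodeError, match="'A'.*'B'"):
            nj_build(m)

    @pytest.mark.parametrize("n_leaves,n_matrices", [(5, 15), (6, 10)])
    def test_exact_on_additive_matrices_vs_ls_oracle(self, n_leaves,
                                                     n_matrices):
        # NJ is exact on additive matrices: the recovered topology must be
        # the least-squares winner over the exhaustive topology list, and
        # tree path lengths must reproduce the input matrix
        bank = TopologyBank()
        rng = random.Random(1234 + n_leaves)
        for _ in range(n_matrices):
            D, true_bips = random_additive_matrix(n_leaves, rng)
            ids = [str(i) for i in range(n_leaves)]
            tree = nj_build(matrix_from_array(ids, D))
            got = {frozenset(int(x) for x in side)
                   for side in named_bipartitions(tree)}
            best_edges, rss = bank.best_topology(D)
            assert rss == pytest.approx(0.0, abs=1e-16)
            assert got == bipartitions_of_edges(best_edges, n_leaves) == \
                {b for b in true_bips}
            names, paths = tree.path_lengths()
            order = [names.index(i) for i in ids]
            assert np.allclose(paths[np.ix_(order, order)], D, atol=1e-9)


@pytest.fixture(scope="module")
def two_clade():
    from coibarcode import TierDivergences
    return simulate(SimulationConfig(
        n_orders=1, families_per_order=1, genera_per_family=1,
        species_per_genus=2, individuals_per_species=4,
        tiers=TierDivergences(0.002, 0.20, 0.25, 0.27, 0.30),
        seed=99))


class TestBootstrap:
    def test_separating_branch_strongly_supported(self, two_clade):
        tree, dropped = bootstrap_support(two_clade.dataset, 100, seed=5)
        assert dropped == 0
        mono = assess_monophyly(tree, two_clade.dataset.taxonomy())
        assert all(m.monophyletic for m in mono)
        supports = [m.support for m in mono if m.support is not None]
        assert supports and min(supports) >= 95.0

    def test_single_replicate_supports_are_0_or_100(self, two_clade):
        tree, _ = bootstrap_support(two_clade.dataset, 1, seed=0)
        sups = [n.support for n in tree.bipartitions().values()]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_same_seed_reproduces_supports(self, two_clade):
        t1, _ = bootstrap_support(two_clade.dataset, 25, seed=11)
        t2, _ = bootstrap_support(two_clade.dataset, 25, seed=11)
        assert to_newick(t1) == to_newick(t2)

    def test_supports_invariant_under_leaf_relabeling(self, two_clade):
        from conftest import make_dataset
        ds = two_clade.dataset
        relabeled = make_dataset(
            {"x_" + r.id: r.sequence for r in ds.records},
            {"x_" + r.id: ("x_" + r.species, r.genus, r.family, r.order)
             for r in ds.records})
        t1, _ = bootstrap_support(ds, 50, seed=21)
        t2, _ = bootstrap_support(relabeled, 50, seed=21)
        s1 = {frozenset("x_" + l for l in side): n.support
              for side, n in t1.bipartitions().items()}
        s2 = {side: n.support for side, n in t2.bipartitions().items()}
        assert s1 == s2

    def test_strong_clade_support_robust_to_column_permutation(self, two_clade):
        from conftest import make_dataset
        ds = two_clade.dataset
        perm = np.random.default_rng(3).permutation(ds.alignment_length)
        permuted = make_dataset(
            {r.id: "".join(r.sequence[c] for c in perm) for r in ds.records},
            ds.taxonomy())
        tree, _ = bootstrap_support(permuted, 100, seed=5)
        mono = assess_monophyly(tree, ds.taxonomy())
        supports = [m.support for m in mono if m.support is not None]
        assert supports and min(supports) >= 95.0


class TestMonophyly:
    def test_two_clade_tree_both_monophyletic(self):
        tree = from_newick("((a1:1,a2:1)90:2,(b1:1,b2:1)80:2,c:3);")
        tax = {x: (x[0].upper(), "G", "F", "O") for x in
               ("a1", "a2", "b1", "b2", "c")}
        mono = {m.species: m for m in assess_monophyly(tree, tax)}
        assert mono["A"].monophyletic and mono["B"].monophyletic
        assert mono["A"].support == pytest.approx(90.0)
        assert mono["B"].support == pytest.approx(80.0)

    def test_interleaved_species_not_monophyletic(self):
        tree = from_newick("((a1:1,b1:1):2,(a2:1,b2:1):2);")
        tax = {x: (x[0].upper(), "G", "F", "O") for x in
               ("a1", "a2", "b1", "b2")}
        mono = {m.species: m for m in assess_monophyly(tree, tax)}
        assert not mono["A"].monophyletic and not mono["B"].monophyletic

    def test_singleton_trivially_monophyletic(self):
        tree = from_newick("((a1:1,a2:1):2,(b1:1,c1:1):2);")
        tax = {"a1": ("A", "G", "F", "O"), "a2": ("A", "G", "F", "O"),
               "b1": ("B", "G", "F", "O"), "c1": ("C", "G", "F", "O")}
        mono = {m.species: m for m in assess_monophyly(tree, tax)}
        assert mono["B"].monophyletic and mono["B"].support is None


class TestNewick:
    def test_format_contract(self, small_sim, small_matrix):
        tree = nj_build(small_matrix)
        text = to_newick(tree)
        assert text.endswith(";") and text.count("(") == text.count(")")

    def test_parse_serialize_round_trip_is_fixed_point(self):
        text = "((a1:1,a2:1.5)88:2,(b1:0.5,b2:1)75:2,c:3);"
        once = to_newick(from_newick(text))
        assert to_newick(from_newick(once)) == once

    def test_output_readable_by_independent_parser(self, small_sim,
                                                    small_matrix):
        # dendropy as an independent reader: leaf set and edge lengths of
        # our serialisation must survive a foreign round trip
        import dendropy

        tree = nj_build(small_matrix)
        dt = dendropy.Tree.get(data=to_newick(tree), schema="newick",
                               preserve_underscores=True)
        assert {l.taxon.label for l in dt.leaf_node_iter()} == \
            set(tree.leaf_names())
        ours = sum(n.length for n in tree.root.walk() if n is not tree.root)
        theirs = dt.length()
        assert theirs == pytest.approx(ours, rel=1e-4)

    def test_names_with_spaces_underscored_or_quoted(self):
        from coibarcode.njtree import PhyloTree, TreeNode
        tree = PhyloTree(TreeNode(children=[
            TreeNode(name="Terapon jarbua", length=1.0),
            TreeNode(name="b", length=1.0),
            TreeNode(name="c", length=1.0)]))
        assert "Terapon_jarbua" in to_newick(tree)
        assert "'Terapon jarbua'" in to_newick(tree, quote_names=True)
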