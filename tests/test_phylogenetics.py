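import math
import random

import numpy as np
import pytest

from wrkytools.phylogenetics import (
    DistanceMatrix,
    bootstrap_support,
    nj_tree,
    p_distance,
    progressive_align,
    tree_from_msa,
)
from wrkytools.tree import TreeNode, parse_newick


def _random_additive_tree(rng, names):
    nodes = [TreeNode(name=n) for n in names]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        a.length = rng.uniform(0.1, 2.0)
        b.length = rng.uniform(0.1, 2.0)
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


def _path_distances(root):
    paths = {}

    def collect(node):
        if node.is_leaf:
            return {node.name: node.length or 0.0}
        out = {}
        subs = [collect(c) for c in node.children]
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                for x, dx in subs[i].items():
                    for y, dy in subs[j].items():
                        paths[frozenset((x, y))] = dx + dy
        for s in subs:
            for x, dx in s.items():
                out[x] = dx + (node.length or 0.0)
        return out

    collect(root)
    return paths


class TestPDistance:
    def test_identical_sequences_zero(self):
        dm = p_distance([("a", "AAAA"), ("b", "AAAA")], model="p")
        assert dm.d[0, 1] == 0.0

    def test_one_in_four(self):
        dm = p_distance([("a", "AAAA"), ("b", "AAAT")], model="p")
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_poisson_correction_closed_form(self):
        dm = p_distance([("a", "AAAA"), ("b", "AAAT")], model="poisson")
        assert dm.d[0, 1] == pytest.approx(-math.log(0.75))

    def test_pairwise_deletion_of_gaps(self):
        dm = p_distance([("a", "A-AA"), ("b", "ATAT")], model="p")
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_sites_names_pair(self):
        with pytest.raises(ValueError, match="a.*b"):
            p_distance([("a", "A--"), ("b", "-AA")], model="p")

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            p_distance([("a", "AA"), ("b", "AAA")])


class TestNeighborJoining:
    def test_four_taxon_exact_lengths(self):
        # distances derived from ((A:1,B:2):1,(C:3,D:4))
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert tree.total_length() == pytest.approx(11.0)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(list("ABC"), d))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx(0.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_fewer_than_three_taxa_raises(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_additive_consistency_100_random_instances(self):
        recovered = 0
        for rep in range(100):
            rng = random.Random(rep)
            true = _random_additive_tree(rng, list("ABCDEF"))
            paths = _path_distances(true)
            names = sorted(l.name for l in true.leaves())
            d = np.zeros((6, 6))
            for i, x in enumerate(names):
                for j, y in enumerate(names):
                    if i < j:
                        d[i, j] = d[j, i] = paths[frozenset((x, y))]
            est = nj_tree(DistanceMatrix(names, d))
            if est.bipartitions() == true.bipartitions():
                recovered += 1
        assert recovered == 100

    def test_tree_length_invariant_under_leaf_permutation(self):
        rng = random.Random(42)
        true = _random_additive_tree(rng, list("ABCDEFG"))
        paths = _path_distances(true)
        names = sorted(l.name for l in true.leaves())
        n = len(names)
        d = np.zeros((n, n))
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i < j:
                    d[i, j] = d[j, i] = paths[frozenset((x, y))]
        base = nj_tree(DistanceMatrix(names, d)).total_length()
        perm = list(range(n))
        rng.shuffle(perm)
        d2 = d[np.ix_(perm, perm)]
        names2 = [names[i] for i in perm]
        assert nj_tree(DistanceMatrix(names2, d2)).total_length() == \
            pytest.approx(base)

    def test_matches_dendropy_on_random_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = random.Random(9)
        true = _random_additive_tree(rng, list("ABCDEFGH"))
        paths = _path_distances(true)
        names = sorted(l.name for l in true.leaves())
        n = len(names)
        csv = "," + ",".join(names) + "\n"
        d = np.zeros((n, n))
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i != j:
                    d[i, j] = paths[frozenset((x, y))]
            csv += x + "," + ",".join(str(v) for v in d[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=io.StringIO(csv))
        ref = pdm.nj_tree()
        ref_splits = set()
        all_names = frozenset(names)
        anchor = min(all_names)
        for node in ref.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            side = all_names - below if anchor in below else below
            if len(side) >= 2 and len(all_names) - len(side) >= 2:
                ref_splits.add(side)
        ours = nj_tree(DistanceMatrix(names, d)).bipartitions()
        assert ours == ref_splits


class TestBootstrap:
    def _two_clade_msa(self, n_diag=200, seed=1):
        rng = np.random.default_rng(seed)
        core = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n_diag))

        def mutate(s, k):
            s = list(s)
            for i in rng.choice(len(s), k, replace=False):
                s[i] = "W" if s[i] != "W" else "Y"
            return "".join(s)

        clade2 = mutate(core, n_diag // 3)
        return [
            ("a1", core), ("a2", mutate(core, 4)),
            ("b1", clade2), ("b2", mutate(clade2, 4)), ("b3", mutate(clade2, 8)),
        ]

    def test_strong_signal_high_support(self):
        msa = self._two_clade_msa()
        tree = bootstrap_support(msa, n_reps=200, seed=3)
        supports = [float(n.name) for n in tree.walk()
                    if not n.is_leaf and n is not tree and n.name]
        assert supports and min(supports) >= 0  # all defined
        clade_supports = [s for s in supports if s > 0]
        assert max(clade_supports) >= 95

    def test_same_seed_reproducible(self):
        msa = self._two_clade_msa()
        t1 = bootstrap_support(msa, n_reps=50, seed=11).to_newick()
        t2 = bootstrap_support(msa, n_reps=50, seed=11).to_newick()
        assert t1 == t2

    def test_identical_sequences_no_crash(self):
        msa = [("a", "MKWL" * 10), ("b", "MKWL" * 10), ("c", "MKWL" * 10),
               ("d", "MKWL" * 10)]
        tree = bootstrap_support(msa, n_reps=20, seed=0)
        assert sorted(tree.leaf_names()) == ["a", "b", "c", "d"]

    def test_supports_within_range(self):
        msa = self._two_clade_msa(seed=7)
        tree = bootstrap_support(msa, n_reps=100, seed=2)
        for node in tree.walk():
            if not node.is_leaf and node is not tree and node.name:
                assert 0.0 <= float(node.name) <= 100.0


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self):
        msa = progressive_align([("a", "MKWVL"), ("b", "MKWVL"), ("c", "MKWVL")])
        assert all(s == "MKWVL" for _, s in msa)

    def test_single_indel_single_gap_column(self):
        msa = dict(progressive_align([("a", "MKLVVF"), ("b", "MKLVF")]))
        assert len(msa["a"]) == 6
        assert msa["b"].count("-") == 1

    def test_alignment_length_at_least_max_input(self):
        seqs = [("a", "MKWVLFG"), ("b", "MKVL"), ("c", "MKWVG")]
        msa = progressive_align(seqs)
        width = len(msa[0][1])
        assert all(len(s) == width for _, s in msa)
        assert width >= max(len(s) for _, s in seqs)

    def test_output_keeps_input_order(self):
        seqs = [("z", "MKWVL"), ("a", "MKWV"), ("m", "MKWL")]
        msa = progressive_align(seqs)
        assert [n for n, _ in msa] == ["z", "a", "m"]

    def test_nj_tree_from_msa_runs(self):
        msa = progressive_align(
            [("a", "MKWVLFGAE"), ("b", "MKWVLFGAE"), ("c", "MKYVLWGAE"),
             ("d", "MKYVLWGA")]
        )
        tree = tree_from_msa(msa, model="p")
        assert sorted(tree.leaf_names()) == ["a", "b", "c", "d"]
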