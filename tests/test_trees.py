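import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average
from scipy.spatial.distance import squareform

from loopinv.distances import DistanceMatrix
from loopinv.records import Alignment
from loopinv.trees import (
    bipartitions,
    bootstrap,
    conspecific_cluster,
    fitch_score,
    nj,
    parsimony_search,
    tree_from_newick,
    tree_path_distances,
    tree_to_newick,
    upgma,
)

from _oracles import enumerate_unrooted, oracle_fitch, oracle_min_parsimony, recompute_q


def _dm(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(ids), d, np.ones_like(d, dtype=int))


def _random_additive(seed, n=6):
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf path-length matrix."""
    rng = np.random.default_rng(seed)
    ids = [f"t{i}" for i in range(n)]
    newick_leaves = list(ids)
    rng.shuffle(newick_leaves)
    # random caterpillar-ish topology by sequential joins
    parts = [f"{x}:{rng.uniform(0.1, 1.0):.4f}" for x in newick_leaves]
    while len(parts) > 3:
        a = parts.pop(int(rng.integers(len(parts))))
        b = parts.pop(int(rng.integers(len(parts))))
        parts.append(f"({a},{b}):{rng.uniform(0.1, 1.0):.4f}")
    tree = tree_from_newick("(" + ",".join(parts) + ");")
    tree.is_rooted = False
    return tree, tree_path_distances(tree)


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = _dm("abc", [[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lengths["b"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert lengths["c"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    @pytest.mark.parametrize("seed", range(6))
    def test_additive_matrix_recovered_exactly(self, seed):
        true_tree, dm = _random_additive(seed)
        est = nj(dm)
        assert bipartitions(est) == bipartitions(true_tree)
        back = tree_path_distances(est)
        np.testing.assert_allclose(back.d, dm.d, atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_each_step_minimizes_q(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        ids = [f"t{i}" for i in range(n)]
        m = rng.uniform(0.1, 1.0, (n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        _, trace = nj(_dm(ids, d), return_trace=True)
        for step in trace:
            assert recompute_q(step["d"], None) == tuple(sorted(step["joined"]))

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 6
        m = rng.uniform(0.1, 1.0, (n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"t{i}" for i in range(n)]
        perm = [4, 2, 0, 5, 1, 3]
        t1 = nj(_dm(ids, d))
        t2 = nj(_dm([ids[i] for i in perm], d[np.ix_(perm, perm)]))
        assert bipartitions(t1) == bipartitions(t2)

    def test_na_rejected(self):
        d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        with pytest.raises(ValueError, match="t0.*t2|t2.*t0"):
            nj(_dm(["t0", "t1", "t2"], d))


class TestUPGMA:
    def test_two_taxa_half_distance(self):
        tree = upgma(_dm("ab", [[0, 0.3], [0.3, 0]]))
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.15)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(1)
        n = 8
        m = rng.uniform(0.2, 1.0, (n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(_dm([f"t{i}" for i in range(n)], d))
        depths = []
        for leaf in tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length
                node = node.parent_node
            depths.append(depth)
        assert max(depths) - min(depths) < 1e-9

    def test_ultrametric_input_recovered(self):
        # heights: (a,b) at 0.1; ((a,b),c) at 0.3; root with d at 0.5
        d = np.array(
            [
                [0.0, 0.2, 0.6, 1.0],
                [0.2, 0.0, 0.6, 1.0],
                [0.6, 0.6, 0.0, 1.0],
                [1.0, 1.0, 1.0, 0.0],
            ]
        )
        tree = upgma(_dm("abcd", d))
        back = tree_path_distances(tree)
        np.testing.assert_allclose(back.d, d[np.ix_([0, 1, 2, 3], [0, 1, 2, 3])], atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_merge_heights_match_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(10 + seed)
        n = 5
        m = rng.uniform(0.2, 1.0, (n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        tree = upgma(_dm([f"t{i}" for i in range(n)], d))
        link = scipy_average(squareform(d))
        my_heights = sorted(
            round(sum(l.edge.length for l in _path_to_root(leaf)), 9)
            for leaf in tree.leaf_node_iter()
        )
        # internal node heights = half the linkage merge distances
        scipy_heights = sorted(link[:, 2] / 2)
        got = sorted(_internal_heights(tree))
        np.testing.assert_allclose(got, scipy_heights, atol=1e-9)


def _path_to_root(leaf):
    node = leaf
    while node.parent_node is not None:
        yield node
        node = node.parent_node


def _internal_heights(tree):
    heights = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaf = next(iter(node.leaf_iter()))
        h, cur = 0.0, leaf
        while cur is not node:
            h += cur.edge.length
            cur = cur.parent_node
        heights.append(round(h, 9))
    return heights


def _aln(rows):
    return Alignment(rows)


class TestFitch:
    def test_invariant_columns_zero(self):
        aln = _aln([("a", "AAA"), ("b", "AAA"), ("c", "AAA"), ("d", "AAA")])
        tree = tree_from_newick("((a,b),(c,d));")
        assert fitch_score(tree, aln) == 0

    def test_single_informative_column(self):
        aln = _aln([("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])
        assert fitch_score(tree_from_newick("((a,b),(c,d));"), aln) == 1
        assert fitch_score(tree_from_newick("((a,c),(b,d));"), aln) == 2

    def test_gap_is_missing_data(self):
        aln = _aln([("a", "A"), ("b", "-"), ("c", "C"), ("d", "C")])
        assert fitch_score(tree_from_newick("((a,b),(c,d));"), aln) == 1

    def test_leaf_mismatch_rejected(self):
        aln = _aln([("a", "A"), ("b", "A"), ("c", "C"), ("x", "C")])
        with pytest.raises(ValueError):
            fitch_score(tree_from_newick("((a,b),(c,d));"), aln)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_oracle_on_all_topologies(self, seed):
        rng = np.random.default_rng(seed)
        n, ncols = 5, 12
        ids = [f"t{i}" for i in range(n)]
        rows = [(t, "".join(rng.choice(list("ACGT-"), ncols))) for t in ids]
        aln = _aln(rows)
        columns = []
        for c in range(ncols):
            col = []
            for _, row in rows:
                ch = row[c]
                col.append({ch} if ch in "ACGT" else {"A", "C", "G", "T"})
            columns.append(col)
        from loopinv.trees import _topology_to_tree

        for topo in enumerate_unrooted(n):
            tree = _topology_to_tree(topo, 0, ids)
            assert fitch_score(tree, aln) == oracle_fitch(topo, 0, columns)

    def test_relabel_permutation_invariance(self):
        rng = np.random.default_rng(8)
        ids = ["a", "b", "c", "d", "e"]
        rows = [(t, "".join(rng.choice(list("ACGT"), 10))) for t in ids]
        aln = _aln(rows)
        tree = tree_from_newick("((a,b),(c,(d,e)));")
        mapping = dict(zip(ids, ["e", "d", "c", "b", "a"]))
        relabelled_tree = tree_from_newick("((e,d),(c,(b,a)));")
        relabelled_rows = [(mapping[t], row) for t, row in rows]
        assert fitch_score(tree, aln) == fitch_score(
            relabelled_tree, _aln(relabelled_rows)
        )


class TestParsimonySearch:
    def _random_alignment(self, seed, n, ncols=15):
        rng = np.random.default_rng(seed)
        ids = [f"t{i}" for i in range(n)]
        return _aln([(t, "".join(rng.choice(list("ACGT"), ncols))) for t in ids])

    @pytest.mark.parametrize("seed", range(3))
    def test_exhaustive_matches_topology_oracle(self, seed):
        aln = self._random_alignment(seed, n=5)
        trees, score = parsimony_search(aln, seed=seed)
        columns = []
        for c in range(aln.n_columns):
            columns.append([{row[c]} for _, row in aln.rows])
        assert score == oracle_min_parsimony(columns, 5)
        for t in trees:
            assert fitch_score(t, aln) == score

    def test_clean_data_recovers_generating_topology(self):
        # two clades separated by many diagnostic sites, no homoplasy
        block_a, block_b = "A" * 10, "C" * 10
        aln = _aln(
            [
                ("a1", block_a + "ACGTACGTAC"),
                ("a2", block_a + "ACGTACGTAA"),
                ("b1", block_b + "ACGAACGTAC"),
                ("b2", block_b + "ACGAACGGAC"),
                ("b3", block_b + "ACGAACGGAA"),
            ]
        )
        trees, _ = parsimony_search(aln, seed=0)
        # canonical form stores the side not containing the smallest leaf id
        want = frozenset({"b1", "b2", "b3"})
        assert all(want in bipartitions(t) for t in trees)

    def test_deterministic_given_seed(self):
        aln = self._random_alignment(4, n=11, ncols=40)
        t1, s1 = parsimony_search(aln, seed=5)
        t2, s2 = parsimony_search(aln, seed=5)
        assert s1 == s2
        assert [tree_to_newick(t) for t in t1] == [tree_to_newick(t) for t in t2]

    def test_heuristic_not_worse_than_nj_start(self):
        aln = self._random_alignment(6, n=12, ncols=60)
        from loopinv.distances import distance_matrix

        start = nj(distance_matrix(aln))
        _, score = parsimony_search(aln, seed=1)
        assert score <= fitch_score(start, aln)


class TestBootstrap:
    def _clade_alignment(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACGT"), 30))
        flip = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[c] for c in base)
        rows = []
        for i in range(3):
            rows.append((f"a{i}", base[:15] + base[15 + i] * 1 + base[16:]))
        for i in range(3):
            rows.append((f"b{i}", flip[:15] + flip[15 + i] * 1 + flip[16:]))
        return _aln(rows)

    def test_identical_rows_degenerate_na(self):
        aln = _aln([(f"r{i}", "ACGTACGT") for i in range(4)])
        _, supports = bootstrap(aln, reps=10, seed=0)
        assert all(math.isnan(v) for v in supports.values())

    def test_clear_separation_high_support(self):
        aln = self._clade_alignment()
        tree, supports = bootstrap(aln, method="nj", reps=100, seed=0)
        split = frozenset({"a0", "a1", "a2"})
        alt = frozenset({"b0", "b1", "b2"})
        key = split if split in supports else alt
        assert supports[key] >= 0.95

    def test_seed_reproducibility(self):
        aln = self._clade_alignment()
        _, s1 = bootstrap(aln, reps=30, seed=7)
        _, s2 = bootstrap(aln, reps=30, seed=7)
        assert s1 == s2

    def test_bad_args(self):
        aln = self._clade_alignment()
        with pytest.raises(ValueError):
            bootstrap(aln, method="mp")
        with pytest.raises(ValueError):
            bootstrap(aln, reps=0)


class TestConspecificCluster:
    def test_adjacent_species_clusters(self):
        tree = tree_from_newick("((a1,a2),(b1,(b2,c1)));")
        smap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        assert conspecific_cluster(tree, smap, "A")

    def test_interleaved_species_does_not(self):
        tree = tree_from_newick("((a1,b1),(a2,(b2,c1)));")
        smap = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        assert not conspecific_cluster(tree, smap, "A")
        assert not conspecific_cluster(tree, smap, "B")

    def test_absent_species_errors(self):
        tree = tree_from_newick("((a1,a2),(b1,b2));")
        with pytest.raises(ValueError):
            conspecific_cluster(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, "Z")


class TestSerialization:
    def test_newick_round_trip(self):
        rng = np.random.default_rng(4)
        n = 6
        m = rng.uniform(0.1, 1.0, (n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        tree = nj(_dm([f"t{i}" for i in range(n)], d))
        back = tree_from_newick(tree_to_newick(tree))
        assert bipartitions(back) == bipartitions(tree)
        d1 = tree_path_distances(tree)
        d2 = tree_path_distances(back)
        np.testing.assert_allclose(d1.d, d2.d, atol=1e-6)
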