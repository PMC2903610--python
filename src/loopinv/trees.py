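"""Distance and parsimony trees, bootstrap support, species clustering.

Neighbor-joining and UPGMA are implemented directly on the p-distance
matrix (canonical Q-criterion / average-linkage agglomeration, lexicographic
tie-breaks so results are invariant to input order). Parsimony uses Fitch
counting, with exhaustive topology enumeration for small datasets and NNI
hill-climbing from the NJ tree otherwise. Trees are dendropy objects, so
newick serialization and taxon bookkeeping follow standard conventions.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import dendropy
import numpy as np

from .distances import DistanceMatrix, distance_matrix
from .records import Alignment

logger = logging.getLogger(__name__)

_STATE = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15


def _check_matrix(dm: DistanceMatrix) -> None:
    if np.isnan(dm.d).any():
        i, j = map(int, np.argwhere(np.isnan(dm.d))[0])
        raise ValueError(f"NA distance between {dm.ids[i]!r} and {dm.ids[j]!r}")


def _new_tree(taxa: list[str]) -> tuple[dendropy.TaxonNamespace, dict[str, dendropy.Node]]:
    tns = dendropy.TaxonNamespace(taxa)
    nodes = {}
    for t in taxa:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(t)
        nodes[t] = node
    return tns, nodes


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("%s: clamped negative branch length %.6g to 0", context, length)
        return 0.0
    return float(length)


def nj(dm: DistanceMatrix, return_trace: bool = False):
    """Neighbor-joining tree (unrooted; basal trifurcation at the seed node).

    At each agglomeration the pair minimizing the Q criterion is joined,
    ties broken lexicographically on the clusters' smallest leaf ids.
    Negative branch lengths are clamped to zero. With ``return_trace`` the
    full working state before each join is also returned, so each step can
    be re-verified externally.
    """
    _check_matrix(dm)
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("nj requires >= 3 taxa")
    tns, leaf_nodes = _new_tree(ids)

    labels = {i: ids[i] for i in range(len(ids))}
    nodes = {i: leaf_nodes[ids[i]] for i in range(len(ids))}
    d = {
        (i, j): float(dm.d[i, j])
        for i, j in combinations(range(len(ids)), 2)
    }

    def dist(i: int, j: int) -> float:
        return d[(i, j) if i < j else (j, i)]

    active = set(range(len(ids)))
    nxt = len(ids)
    trace = []
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for i, j in combinations(sorted(active, key=lambda x: labels[x]), 2):
            q = (r - 2) * dist(i, j) - sums[i] - sums[j]
            if q < best_q - 1e-12:
                best_q, best = q, (i, j)
        i, j = best
        if return_trace:
            trace.append(
                {
                    "active": {labels[k]: k for k in active},
                    "labels": dict(labels),
                    "d": {
                        tuple(sorted((labels[a], labels[b]))): dist(a, b)
                        for a, b in combinations(sorted(active), 2)
                    },
                    "joined": (labels[i], labels[j]),
                }
            )
        li = dist(i, j) / 2 + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dist(i, j) - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _clamp(li, "nj")
        nodes[j].edge.length = _clamp(lj, "nj")
        for k in active:
            if k in (i, j):
                continue
            duk = (dist(i, k) + dist(j, k) - dist(i, j)) / 2
            d[(min(nxt, k), max(nxt, k))] = duk
        nodes[nxt] = parent
        labels[nxt] = min(labels[i], labels[j])
        active -= {i, j}
        active.add(nxt)
        nxt += 1

    # three-point closed form for the final trifurcation
    a, b, c = sorted(active, key=lambda x: labels[x])
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    seed = dendropy.Node()
    for node_idx, ln in ((a, la), (b, lb), (c, lc)):
        seed.add_child(nodes[node_idx])
        nodes[node_idx].edge.length = _clamp(ln, "nj")
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    if return_trace:
        return tree, trace
    return tree


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Rooted ultrametric tree by average linkage; heights are d/2."""
    _check_matrix(dm)
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("upgma requires >= 2 taxa")
    tns, leaf_nodes = _new_tree(ids)
    labels = {i: ids[i] for i in range(len(ids))}
    nodes = {i: leaf_nodes[ids[i]] for i in range(len(ids))}
    heights = {i: 0.0 for i in range(len(ids))}
    sizes = {i: 1 for i in range(len(ids))}
    d = {(i, j): float(dm.d[i, j]) for i, j in combinations(range(len(ids)), 2)}

    def dist(i, j):
        return d[(i, j) if i < j else (j, i)]

    active = set(range(len(ids)))
    nxt = len(ids)
    while len(active) > 1:
        i, j = min(
            (tuple(sorted(p, key=lambda x: labels[x])) for p in combinations(active, 2)),
            key=lambda p: (dist(*p), labels[p[0]], labels[p[1]]),
        )
        h = dist(i, j) / 2
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _clamp(h - heights[i], "upgma")
        nodes[j].edge.length = _clamp(h - heights[j], "upgma")
        for k in active:
            if k in (i, j):
                continue
            duk = (dist(i, k) * sizes[i] + dist(j, k) * sizes[j]) / (
                sizes[i] + sizes[j]
            )
            d[(min(nxt, k), max(nxt, k))] = duk
        nodes[nxt] = parent
        heights[nxt] = h
        sizes[nxt] = sizes[i] + sizes[j]
        labels[nxt] = min(labels[i], labels[j])
        active -= {i, j}
        active.add(nxt)
        nxt += 1
    root = nodes[nxt - 1]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


def _column_states(alignment: Alignment) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-leaf state masks for distinct column patterns, with weights."""
    ids = alignment.ids
    mat = np.zeros((len(ids), alignment.n_columns), dtype=np.uint8)
    for r, (_, row) in enumerate(alignment.rows):
        for c, ch in enumerate(row):
            mat[r, c] = _STATE.get(ch, _MISSING)
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return ids, patterns, weights.astype(np.int64)


def _fitch_masks(children_masks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Fold children left to right; returns (state mask, change count per column)."""
    state = children_masks[0]
    changes = np.zeros(state.shape, dtype=np.int64)
    for child in children_masks[1:]:
        inter = state & child
        union = state | child
        miss = inter == 0
        changes = changes + miss.astype(np.int64)
        state = np.where(miss, union, inter).astype(np.uint8)
    return state, changes


def fitch_score(tree: dendropy.Tree, alignment: Alignment) -> int:
    """Minimum number of state changes over all columns (gaps = missing data)."""
    ids, patterns, weights = _column_states(alignment)
    idx = {t: i for i, t in enumerate(ids)}
    tree_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tree_labels != set(ids):
        raise ValueError("tree leaves do not match alignment rows")
    total = np.zeros(patterns.shape[1], dtype=np.int64)
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = patterns[idx[node.taxon.label]]
        else:
            childs = [masks.pop(id(c)) for c in node.child_nodes()]
            state, changes = _fitch_masks(childs)
            masks[id(node)] = state
            total += changes
    return int((total * weights).sum())


# ---- exhaustive/heuristic parsimony -------------------------------------

# Internal light-weight topology representation: an unrooted tree on leaves
# 0..n-1 is stored as a rooted binary structure over leaves 1..n-1 (nested
# tuples), implicitly joined to leaf 0 at the root edge.


def _enumerate_rooted(leaves: list[int]):
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for sub in _enumerate_rooted(rest):
        for t in _insert_everywhere(sub, first):
            yield t


def _insert_everywhere(tree, leaf):
    yield (leaf, tree)
    if isinstance(tree, tuple):
        left, right = tree
        for nl in _insert_everywhere(left, leaf):
            yield (nl, right)
        for nr in _insert_everywhere(right, leaf):
            yield (left, nr)


def _score_topology(tree, leaf0: int, patterns: np.ndarray, weights: np.ndarray) -> int:
    def rec(node) -> tuple[np.ndarray, np.ndarray]:
        if not isinstance(node, tuple):
            return patterns[node], np.zeros(patterns.shape[1], dtype=np.int64)
        (s1, c1), (s2, c2) = rec(node[0]), rec(node[1])
        state, extra = _fitch_masks([s1, s2])
        return state, c1 + c2 + extra
    state, changes = rec(tree)
    _, extra = _fitch_masks([state, patterns[leaf0]])
    return int(((changes + extra) * weights).sum())


def _topology_to_tree(tree, leaf0: int, ids: list[str]) -> dendropy.Tree:
    def rec(node) -> str:
        if not isinstance(node, tuple):
            return ids[node]
        return f"({rec(node[0])},{rec(node[1])})"
    if isinstance(tree, tuple):
        newick = f"({ids[leaf0]},{rec(tree[0])},{rec(tree[1])});"
    else:
        newick = f"({ids[leaf0]},{rec(tree)});"
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = False
    return t


def _nni_neighbors(tree):
    """All NNI rearrangements of a nested-tuple rooted topology."""
    out = []

    def rec(node, rebuild):
        if not isinstance(node, tuple):
            return
        left, right = node
        if isinstance(left, tuple):
            a, b = left
            out.append(rebuild(((a, right), b)))
            out.append(rebuild(((b, right), a)))
            rec(left, lambda sub: rebuild((sub, right)))
        if isinstance(right, tuple):
            c, dd = right
            out.append(rebuild((c, (left, dd))))
            out.append(rebuild((dd, (left, c))))
            rec(right, lambda sub: rebuild((left, sub)))

    rec(tree, lambda x: x)
    return out


def _tree_to_topology(tree: dendropy.Tree, ids: list[str]):
    """Convert a dendropy tree to the nested-tuple representation rooted at ids[0]."""
    index = {t: i for i, t in enumerate(ids)}
    t = tree.clone(depth=1)
    leaf0 = None
    for leaf in t.leaf_node_iter():
        if leaf.taxon.label == ids[0]:
            leaf0 = leaf
            break
    t.reroot_at_edge(leaf0.edge)
    # root now has leaf0 and the rest
    def rec(node):
        if node.is_leaf():
            return index[node.taxon.label]
        kids = node.child_nodes()
        sub = rec(kids[0])
        for k in kids[1:]:
            sub = (sub, rec(k))
        return sub
    others = [c for c in t.seed_node.child_nodes() if c is not leaf0]
    sub = rec(others[0])
    for o in others[1:]:
        sub = (sub, rec(o))
    return sub


def parsimony_search(
    alignment: Alignment,
    max_trees: int = 5000,
    seed: int = 0,
    exhaustive_limit: int = 9,
) -> tuple[list[dendropy.Tree], int]:
    """Most-parsimonious trees under Fitch counting.

    Exhaustive over all unrooted topologies up to ``exhaustive_limit`` taxa;
    otherwise NNI hill-climbing from the NJ tree with a seeded tie-breaking
    order. The returned set is capped at ``max_trees``.
    """
    ids, patterns, weights = _column_states(alignment)
    n = len(ids)
    if n < 4:
        raise ValueError("parsimony_search requires >= 4 taxa")
    if n <= exhaustive_limit:
        best_score = None
        best: list = []
        for topo in _enumerate_rooted(list(range(1, n))):
            s = _score_topology(topo, 0, patterns, weights)
            if best_score is None or s < best_score:
                best_score, best = s, [topo]
            elif s == best_score and len(best) < max_trees:
                best.append(topo)
        trees = [_topology_to_tree(t, 0, ids) for t in best]
        return trees, int(best_score)

    rng = np.random.default_rng(seed)
    dm = distance_matrix(alignment)
    start = _tree_to_topology(nj(dm), ids)
    cur = start
    cur_score = _score_topology(cur, 0, patterns, weights)
    while True:
        neighbors = _nni_neighbors(cur)
        order = rng.permutation(len(neighbors))
        improved = False
        for k in order:
            s = _score_topology(neighbors[k], 0, patterns, weights)
            if s < cur_score:
                cur, cur_score = neighbors[k], s
                improved = True
                break
        if not improved:
            break
    best_set = {cur}
    for nb in _nni_neighbors(cur):
        if len(best_set) >= max_trees:
            break
        if _score_topology(nb, 0, patterns, weights) == cur_score:
            best_set.add(nb)
    trees = [_topology_to_tree(t, 0, ids) for t in sorted(best_set, key=repr)]
    return trees, int(cur_score)


# ---- bipartitions, bootstrap, clustering --------------------------------


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the side not holding the
    lexicographically smallest leaf id (a rooting-free canonical form)."""
    all_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = below if anchor not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(frozenset(side))
    return out


def bootstrap(
    alignment: Alignment,
    method: str = "nj",
    reps: int = 100,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Column-resampling bootstrap support for the original tree's edges.

    On degenerate data (no variable sites) supports are reported as NaN.
    """
    if method not in ("nj", "upgma"):
        raise ValueError("method must be 'nj' or 'upgma'")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    build = nj if method == "nj" else upgma
    dm = distance_matrix(alignment)
    tree = build(dm)
    orig = bipartitions(tree)
    from .distances import variable_sites as _vs

    nvar, _ = _vs([row for _, row in alignment.rows], gap_mode="pairwise_deletion")
    if nvar == 0:
        logger.warning("bootstrap: no variable sites; supports undefined")
        return tree, {bp: math.nan for bp in orig}
    rng = np.random.default_rng(seed)
    counts = {bp: 0 for bp in orig}
    ncols = alignment.n_columns
    ok_reps = 0
    for _ in range(reps):
        cols = rng.integers(0, ncols, size=ncols)
        rows = [
            (rid, "".join(row[c] for c in cols)) for rid, row in alignment.rows
        ]
        try:
            rep_tree = build(distance_matrix(Alignment(rows)))
        except ValueError:
            continue
        ok_reps += 1
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if ok_reps == 0:
        return tree, {bp: math.nan for bp in orig}
    return tree, {bp: counts[bp] / ok_reps for bp in counts}


def conspecific_cluster(
    tree: dendropy.Tree, species_map: dict[str, str], species: str
) -> bool:
    """True iff one edge of the unrooted tree separates exactly this
    species' leaves from all others."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    target = {rid for rid, sp in species_map.items() if sp == species and rid in leaves}
    if not target:
        raise ValueError(f"species {species!r} absent from tree")
    if len(target) < 2:
        raise ValueError(f"species {species!r} has fewer than 2 leaves")
    if target == leaves:
        return True
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == target or (leaves - below) == target:
            return True
    return False


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tree_from_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix (for additivity/ultrametricity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    ids = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    tns = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.distance(tns[ids[i]], tns[ids[j]])
    return DistanceMatrix(ids, d, np.zeros((n, n), dtype=int))


def write_support_table(
    supports: dict[frozenset, float], path
) -> None:
    with open(path, "w") as fh:
        fh.write("bipartition\tsupport\n")
        for bp in sorted(supports, key=lambda s: (len(s), sorted(s))):
            fh.write(f"{','.join(sorted(bp))}\t{supports[bp]}\n")
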