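"""Independent brute-force oracles used to validate the implementations.

These deliberately use different mechanisms from the package code paths
(pair matrices and vectorized diagonal scans instead of outward walks;
explicit enumeration of alignments and topologies instead of DP/heuristics).
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_hairpins(
    seq: str, min_arm: int, max_loop: int, max_arm_mismatch: int
) -> set[tuple[int, int, int, int]]:
    """All maximal hairpins as (loop_start, loop_end, arm_len, mismatches).

    Enumerates every loop interval and scans its anti-diagonal of the pair
    matrix: an arm of length L is valid when its innermost and outermost
    pairs complement and its interior mismatches stay within budget; the
    maximal valid L per loop interval is reported.
    """
    n = len(seq)
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_enc = np.zeros(n, dtype=np.uint8)
    for base, cb in _COMP.items():
        comp_enc[enc == ord(base)] = ord(cb)
    comp = enc[None, :] == comp_enc[:, None]  # comp[p, q]: q complements p
    out = set()
    for ls in range(1, n):
        for ll in range(0, max_loop + 1):
            le = ls + ll
            if le >= n:
                break
            tmax = min(ls, n - le)
            if tmax < min_arm:
                continue
            pairs = comp[ls - 1 - np.arange(tmax), le + np.arange(tmax)]
            if not pairs[0]:
                continue
            mism = np.cumsum(~pairs)
            valid = np.flatnonzero(pairs & (mism <= max_arm_mismatch))
            if valid.size == 0:
                continue
            L = int(valid[-1]) + 1
            if L >= min_arm:
                out.add((ls, le, L, int(mism[valid[-1]])))
    return out


def oracle_align_score(a: str, b: str, params) -> float:
    """Maximum global affine-gap alignment score by explicit enumeration of
    all alignments (op strings over M/X/Y), small inputs only."""
    best = [-np.inf]

    def score_run(length: int, at_start: bool, at_end: bool) -> float:
        if params.terminal_gaps_free and (at_start or at_end):
            return 0.0
        return params.gap_open + (length - 1) * params.gap_extend

    def rec(i, j, ops):
        if i == len(a) and j == len(b):
            # score this complete alignment
            s = 0.0
            k = 0
            ai = bi = 0
            while k < len(ops):
                op = ops[k]
                if op == "M":
                    s += params.match if a[ai] == b[bi] else params.mismatch
                    ai += 1
                    bi += 1
                    k += 1
                else:
                    k2 = k
                    while k2 < len(ops) and ops[k2] == op:
                        k2 += 1
                    run = k2 - k
                    s -= score_run(run, k == 0, k2 == len(ops))
                    if op == "X":
                        bi += run
                    else:
                        ai += run
                    k = k2
            best[0] = max(best[0], s)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ops + "M")
        if j < len(b):
            rec(i, j + 1, ops + "X")
        if i < len(a):
            rec(i + 1, j, ops + "Y")

    rec(0, 0, "")
    return best[0]


def enumerate_unrooted(n: int):
    """All unrooted binary topologies on leaves 0..n-1, as nested tuples
    rooted at leaf 0 (the remaining structure spans leaves 1..n-1)."""

    def rec(leaves):
        if len(leaves) == 1:
            yield leaves[0]
            return
        head, rest = leaves[0], leaves[1:]
        for sub in rec(rest):
            yield from insertions(sub, head)

    def insertions(tree, leaf):
        yield (leaf, tree)
        if isinstance(tree, tuple):
            l, r = tree
            for nl in insertions(l, leaf):
                yield (nl, r)
            for nr in insertions(r, leaf):
                yield (l, nr)

    yield from rec(list(range(1, n)))


def oracle_fitch(topology, leaf0: int, columns: list[list[set]]) -> int:
    """Set-based Fitch count over columns; columns[c][leaf] is the state set."""
    total = 0
    for col in columns:
        changes = 0

        def rec(node):
            nonlocal changes
            if not isinstance(node, tuple):
                return set(col[node])
            s1, s2 = rec(node[0]), rec(node[1])
            inter = s1 & s2
            if inter:
                return inter
            changes += 1
            return s1 | s2

        root_set = rec(topology)
        if not (root_set & col[leaf0]):
            changes += 1
        total += changes
    return total


def oracle_min_parsimony(columns: list[list[set]], n_leaves: int) -> int:
    return min(
        oracle_fitch(t, 0, columns) for t in enumerate_unrooted(n_leaves)
    )


def recompute_q(d: dict, labels_of: list) -> tuple:
    """Independent Q-matrix scan for one NJ step: d maps (label_a, label_b)
    (lexicographically ordered) to distances; returns the Q-minimal pair."""
    labels = sorted({x for pair in d for x in pair})
    r = len(labels)
    sums = {
        a: sum(d[tuple(sorted((a, b)))] for b in labels if b != a) for a in labels
    }
    best, best_q = None, np.inf
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            q = (r - 2) * d[tuple(sorted((a, b)))] - sums[a] - sums[b]
            if q < best_q - 1e-12:
                best_q, best = q, (a, b)
    return best
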