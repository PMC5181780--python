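"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive pure Python, sharing no code with the
package: exhaustive enumeration of global alignments, a textbook three-state
affine DP, substring-pair local optima, and additive distance matrices from
random trees.
"""

from __future__ import annotations

import random

NEG = float("-inf")


def enumerate_global(a, b, score, gap_open, gap_extend):
    """Optimal global affine-gap score by exhaustive enumeration of every
    alignment path (gap of length L costs gap_open + L * gap_extend)."""
    first = gap_open + gap_extend
    best = NEG
    la, lb = len(a), len(b)

    def rec(i, j, acc, last):
        nonlocal best
        if i == la and j == lb:
            if acc > best:
                best = acc
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, acc + score[a[i], b[j]], "D")
        if i < la:
            rec(i + 1, j, acc - (gap_extend if last == "U" else first), "U")
        if j < lb:
            rec(i, j + 1, acc - (gap_extend if last == "L" else first), "L")

    rec(0, 0, 0.0, None)
    return best


def gotoh_global(a, b, score, gap_open, gap_extend):
    """Textbook three-state (M/Ix/Iy) global affine DP."""
    first = gap_open + gap_extend
    la, lb = len(a), len(b)
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Ix = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(la + 1):
        for j in range(lb + 1):
            if i >= 1 and j >= 1:
                prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
                if prev > NEG:
                    M[i][j] = prev + score[a[i - 1], b[j - 1]]
            if i >= 1:
                Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend,
                               Iy[i - 1][j] - first)
            if j >= 1:
                Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend,
                               Ix[i][j - 1] - first)
    return max(M[la][lb], Ix[la][lb], Iy[la][lb])


def local_by_substrings(a, b, score, gap_open, gap_extend):
    """Optimal local score = best global score over all substring pairs
    (empty alignment allowed: never below 0)."""
    best = 0.0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for m in range(j + 1, len(b) + 1):
                    s = gotoh_global(a[i:k], b[j:m], score, gap_open, gap_extend)
                    if s > best:
                        best = s
    return best


def random_additive_tree(n_taxa: int, rng: random.Random):
    """A random unrooted binary tree topology with positive branch lengths.

    Returns (edges, taxa, distances) where distances is the additive path
    metric between all taxa, scaled so every entry lies in (0, 1].
    """
    taxa = [f"t{i}" for i in range(n_taxa)]
    # adjacency: node -> {neighbor: length}; internal nodes get negative ids
    adj: dict = {}
    nxt = [-1]

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def new_internal():
        nxt[0] -= 1
        return nxt[0]

    def blen():
        return rng.uniform(0.05, 0.5)

    center = -1
    adj[center] = {}
    for t in taxa[:3]:
        connect(center, t, blen())
    for t in taxa[3:]:
        edges = []
        seen_edges = set()
        for u in adj:
            for v in adj[u]:
                if (repr(v), repr(u)) not in seen_edges:
                    seen_edges.add((repr(u), repr(v)))
                    edges.append((u, v))
        u, v = rng.choice(sorted(edges, key=repr))
        w = adj[u][v]
        mid = new_internal()
        split = rng.uniform(0.2, 0.8) * w
        del adj[u][v]
        del adj[v][u]
        connect(u, mid, split)
        connect(mid, v, w - split)
        connect(mid, t, blen())

    def dists_from(src):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        return seen

    dist = {}
    for t in taxa:
        d = dists_from(t)
        for u in taxa:
            dist[t, u] = d[u]
    scale = max(dist.values())
    dist = {k: v / (scale * 1.01) for k, v in dist.items()}
    splits = tree_splits(adj, taxa)
    return dist, taxa, splits


def tree_splits(adj, taxa):
    """Non-trivial bipartitions of an unrooted tree given as adjacency."""
    taxa_set = frozenset(taxa)
    splits = set()
    for u in adj:
        for v in adj[u]:
            # leaves on v's side when edge (u, v) is cut
            side = set()
            stack = [v]
            seen = {u, v}
            while stack:
                x = stack.pop()
                if isinstance(x, str):
                    side.add(x)
                for y in adj.get(x, {}):
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            side = frozenset(side)
            if 1 < len(side) < len(taxa) - 1:
                splits.add(frozenset({side, taxa_set - side}))
    return splits


def skbio_tree_splits(tree, taxa):
    """Non-trivial bipartitions of an skbio TreeNode."""
    taxa_set = frozenset(taxa)
    splits = set()
    for subset in tree.subsets():
        side = frozenset(subset)
        if 1 < len(side) < len(taxa) - 1:
            splits.add(frozenset({side, taxa_set - side}))
    return splits
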