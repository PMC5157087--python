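"""Independent oracles used by the test suite.

Each oracle deliberately re-derives a quantity through a different route
than the package: a plain-python Gotoh matrix recurrence for local alignment
scores, hypergeometric enumeration for Fisher's exact test, the step-up
formula for Benjamini-Hochberg, dendropy-based bipartition enumeration for
monophyly, and path-length matrices from explicitly constructed additive
trees for neighbor joining.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: int = 11,
                    gap_extend: int = 1) -> float:
    """Plain-python Smith-Waterman-Gotoh best local score.

    Gap cost convention: a gap of length L costs gap_open + L * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first_gap, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first_gap, F[i - 1][j] - gap_extend)
            s = _B62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration.

    Sums the probabilities of every table with the same margins whose
    probability does not exceed (up to float slack) that of the observed
    table.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_p(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (math.lgamma(r1 + 1) - math.lgamma(x + 1)
                - math.lgamma(r1 - x + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
                - math.lgamma(r2 - c1 + x + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1)
                   - math.lgamma(n - c1 + 1)))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    lp_obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= lp_obs + 1e-7:
            total += math.exp(lp)
    return min(1.0, total)


def bh_oracle(pvec) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(pvec, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary unrooted tree with positive branch lengths.

    Returns (labels, distance matrix, set of non-trivial splits as
    frozensets of labels).  Built by sequential taxon attachment on an
    explicit edge list; distances are path lengths.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (node, length); leaves are labels,
    # internal nodes are ints
    adj: dict = {labels[0]: [], labels[1]: [], labels[2]: [], 0: []}
    nxt = 1

    def connect(u, v, w):
        adj[u].append((v, w))
        adj[v].append((u, w))

    for leaf in labels[:3]:
        connect(leaf, 0, float(rng.uniform(0.1, 1.0)))
    edges = [(labels[0], 0), (labels[1], 0), (labels[2], 0)]
    for leaf in labels[3:]:
        u, v = edges[rng.integers(0, len(edges))]
        w = next(wt for (x, wt) in adj[u] if x == v)
        adj[u] = [(x, wt) for (x, wt) in adj[u] if x != v]
        adj[v] = [(x, wt) for (x, wt) in adj[v] if x != u]
        mid = nxt
        nxt += 1
        adj[mid] = []
        f = float(rng.uniform(0.2, 0.8))
        connect(u, mid, w * f)
        connect(v, mid, w * (1 - f))
        adj[leaf] = []
        connect(leaf, mid, float(rng.uniform(0.1, 1.0)))
        edges.remove((u, v) if (u, v) in edges else (v, u))
        edges.extend([(u, mid), (v, mid), (leaf, mid)])
    # path distances by BFS from each leaf
    d = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    d = (d + d.T) / 2.0  # float addition order makes tiny asymmetries
    np.fill_diagonal(d, 0.0)
    # splits: remove each internal edge, collect leaf side
    splits = set()
    for u in adj:
        for v, _w in adj[u]:
            if isinstance(u, int) and isinstance(v, int) and u < v:
                side = set()
                stack = [(u, v)]
                seen = {v}
                stack = [u]
                while stack:
                    x = stack.pop()
                    if x in seen:
                        continue
                    seen.add(x)
                    if isinstance(x, str):
                        side.add(x)
                    else:
                        stack.extend(y for y, _ in adj[x])
                if 2 <= len(side) <= n_taxa - 2:
                    splits.add(frozenset(side))
    return labels, d, splits


def tree_splits(sides: list, leaves: frozenset) -> set:
    """Canonical non-trivial splits (smaller-or-lexic side) from edge sides."""
    out = set()
    for s in sides:
        comp = leaves - s
        if len(s) < 2 or len(comp) < 2:
            continue
        out.add(min(frozenset(s), frozenset(comp),
                    key=lambda x: (len(x), tuple(sorted(x)))))
    return out


def monophyly_oracle(newick: str, query: str, donor_taxon: str,
                     taxon_of: dict) -> bool:
    """Exhaustive bipartition enumeration on a dendropy-parsed tree.

    Independent re-statement of the minimal-side rule: among all edge sides
    containing the query with >= 2 leaves (plus the full leaf set), every
    smallest side must contain only donor-taxon leaves besides the query.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    sides = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.append(side)
    qsides = []
    for side in sides:
        qside = side if query in side else leaves - side
        if len(qside) >= 2:
            qsides.append(qside)
    qsides.append(leaves)
    msize = min(len(s) for s in qsides)
    return all(
        all(taxon_of[x] == donor_taxon for x in s if x != query)
        for s in qsides if len(s) == msize)
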