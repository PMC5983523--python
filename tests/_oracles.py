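"""Independent oracles used by the test suite.

Everything here is deliberately naive and separate from the package's
implementation paths: a per-pair K2P recomputation in pure Python, an
exhaustive enumeration of unrooted binary topologies with least-squares
branch fitting (the classic check that neighbor joining is exact on
additive matrices), and random additive matrix generation from random
trees.
"""

from __future__ import annotations

import itertools
import math
import random

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def k2p_by_hand(seq_a: str, seq_b: str):
    """(P, Q, d or None) computed with explicit per-site bookkeeping."""
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return P, Q, None
    return P, Q, -0.5 * math.log(w1 * math.sqrt(w2))


# ---------------------------------------------------------------------------
# unrooted topology enumeration + least squares
# ---------------------------------------------------------------------------

def enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies over leaves 0..n-1 as edge lists.

    Built by the standard stepwise insertion: leaf k is attached to every
    edge of every (k-1)-leaf tree.  Node ids >= n_leaves are internal.
    Counts: 3 leaves -> 1, 5 -> 15, 6 -> 105, 7 -> 945, 8 -> 10395.
    """
    assert n_leaves >= 3
    # internal node ids start at n_leaves to avoid colliding with leaves
    trees = [([(0, n_leaves), (1, n_leaves), (2, n_leaves)], n_leaves + 1)]
    for leaf in range(3, n_leaves):
        new_trees = []
        for edges, nxt in trees:
            for i, (u, v) in enumerate(edges):
                new_edges = edges[:i] + edges[i + 1:]
                new_edges += [(u, nxt), (nxt, v), (leaf, nxt)]
                new_trees.append((new_edges, nxt + 1))
        trees = new_trees
    return [edges for edges, _ in trees]


def _paths(edges, n_leaves: int):
    """0/1 design matrix: one row per leaf pair, one column per edge."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path_edges(a, b):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, used = stack.pop()
            if node == b:
                return used
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, used + [eidx]))
        raise AssertionError("disconnected tree")

    pairs = list(itertools.combinations(range(n_leaves), 2))
    X = np.zeros((len(pairs), len(edges)))
    for r, (a, b) in enumerate(pairs):
        for eidx in path_edges(a, b):
            X[r, eidx] = 1.0
    return X


class TopologyBank:
    """Cached per-leaf-count topologies with pseudoinverse path designs,
    so least-squares RSS per candidate topology is a matrix multiply."""

    def __init__(self):
        self._bank: dict[int, list] = {}

    def get(self, n_leaves: int):
        if n_leaves not in self._bank:
            entries = []
            for edges in enumerate_topologies(n_leaves):
                X = _paths(edges, n_leaves)
                # hat matrix for RSS without solving per matrix
                H = X @ np.linalg.pinv(X)
                entries.append((edges, X, H))
            self._bank[n_leaves] = entries
        return self._bank[n_leaves]

    def best_topology(self, D: np.ndarray):
        """Edges of the minimum-RSS topology for distance matrix D."""
        n = D.shape[0]
        iu = np.triu_indices(n, 1)
        d = D[iu]
        best, best_rss = None, None
        for edges, X, H in self.get(n):
            resid = d - H @ d
            rss = float(resid @ resid)
            if best_rss is None or rss < best_rss:
                best, best_rss = edges, rss
        return best, best_rss


def bipartitions_of_edges(edges, n_leaves: int):
    """Nontrivial bipartitions (as frozensets of the side without leaf 0)."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    out = set()
    for u, v in edges:
        # leaves on v's side when edge (u,v) is removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n_leaves:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 2 <= len(side) <= n_leaves - 2:
            if 0 in side:
                side = set(range(n_leaves)) - side
            out.add(frozenset(side))
    return out


def random_additive_matrix(n_leaves: int, rng: random.Random,
                           min_len: float = 0.05, max_len: float = 1.0):
    """Random unrooted binary tree -> (distance matrix, true bipartitions)."""
    topologies = None  # built on the fly: random stepwise insertion
    edges = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    nxt = n_leaves + 1
    for leaf in range(3, n_leaves):
        i = rng.randrange(len(edges))
        u, v = edges.pop(i)
        edges += [(u, nxt), (nxt, v), (leaf, nxt)]
        nxt += 1
    lengths = {e: rng.uniform(min_len, max_len) for e in edges}

    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in lengths.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    D = np.zeros((n_leaves, n_leaves))
    for a in range(n_leaves):
        dist = {a: 0.0}
        stack = [a]
        while stack:
            node = stack.pop()
            for nxt_node, w in adj[node]:
                if nxt_node not in dist:
                    dist[nxt_node] = dist[node] + w
                    stack.append(nxt_node)
        for b in range(n_leaves):
            D[a, b] = dist[b]
    return D, bipartitions_of_edges(edges, n_leaves)
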