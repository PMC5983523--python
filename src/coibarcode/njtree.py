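"""Neighbor-joining trees, bootstrap supports and monophyly assessment.

Classic neighbor joining (Saitou–Nei agglomeration on the Q-criterion)
over the K2P distance matrix, a nonparametric bootstrap that resamples
alignment columns with replacement and maps bipartition frequencies onto
the original tree, deterministic Newick serialisation, and an unrooted
monophyly test per species.

Conventions, chosen for determinism and stated rather than inferred:

* Q-criterion ties are broken by the smallest (row, column) index pair in
  the current matrix order; ties genuinely occur with duplicated
  sequences.
* A negative branch length produced by the two-point formulas is clamped
  to zero and the deficit is transferred to its sister branch, so the
  joined pair's path length is preserved.
* The final three lineages are resolved by the three-point closed form,
  giving an unrooted tree whose internal nodes all have degree three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seqcodes import encode_alignment
from .barcode_io import BarcodeDataset, BarcodeError
from .divergence import DistanceMatrix, distance_matrix, k2p_matrix_from_codes

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    """A node of an (un)rooted tree; ``length`` is the branch above it."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary trifurcating root."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Map each internal branch to the bipartition it induces.

        Keys are canonical sides: the leaf set *not* containing the
        lexicographically smallest leaf, so bipartitions compare equal
        across trees over the same leaves.  Trivial (leaf) branches are
        excluded.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            below = frozenset(node.leaf_names())
            if len(below) < 2 or len(all_leaves - below) < 2:
                continue
            canon = all_leaves - below if ref in below else below
            out[canon] = node
        return out

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix (tests additivity)."""
        names = sorted(self.leaf_names())
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        dist = np.zeros((n, n))

        def below(node):
            """Return {leaf_index: distance to this node}."""
            if node.is_leaf:
                return {index[node.name]: 0.0}
            merged: dict[int, float] = {}
            child_maps = []
            for ch in node.children:
                m = {k: v + ch.length for k, v in below(ch).items()}
                child_maps.append(m)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for i, di in child_maps[a].items():
                        for j, dj in child_maps[b].items():
                            dist[i, j] = dist[j, i] = di + dj
            for m in child_maps:
                merged.update(m)
            return merged

        below(self.root)
        return names, dist


@dataclass(frozen=True)
class MonophylyRecord:
    species: str
    n_individuals: int
    monophyletic: bool
    support: float | None  # % of bootstrap replicates; None if n/a


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to the sister."""
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def nj_build(matrix: DistanceMatrix) -> PhyloTree:
    """Classic neighbor joining on a fully defined distance matrix.

    Iteratively joins the pair (i, j) minimising
    ``Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``
    with branch lengths from the standard two-point formulas; the last
    three lineages are resolved by the three-point closed form.
    """
    n = len(matrix.ids)
    if n < 3:
        raise BarcodeError("neighbor joining needs at least 3 sequences")
    if matrix.n_undefined_pairs:
        pair = matrix.undefined_pairs()[0]
        raise BarcodeError(
            f"undefined (saturated) distance between {pair[0]!r} and "
            f"{pair[1]!r}; cannot build a tree"
        )
    D = matrix.d.copy()
    nodes = [TreeNode(name=rid) for rid in matrix.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major: ties resolve to the smallest (row, col)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])

        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       du[keep][None, :]])
        D = np.hstack([D, np.append(du[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = D[0, 1] - la
    lc = D[0, 2] - la
    a.length = max(la, 0.0)
    b.length = max(lb, 0.0)
    c.length = max(lc, 0.0)
    return PhyloTree(TreeNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class BootstrapError(BarcodeError):
    """Too many replicates dropped for saturation/undefined distances."""


def bootstrap_support(dataset: BarcodeDataset, n_replicates: int,
                      seed: int | None, block: int = 1,
                      tree: PhyloTree | None = None,
                      ) -> tuple[PhyloTree, int]:
    """Nonparametric bootstrap supports mapped onto the original NJ tree.

    Each replicate resamples alignment columns with replacement (or codon
    triplets when ``block=3``), recomputes the K2P matrix and NJ tree, and
    counts which bipartitions of the original tree reappear.  Supports are
    percentages of valid replicates.  Replicates with any saturated
    distance are dropped and counted; more than 10% dropped is an error.

    Returns the tree (supports attached in place if one was passed) and
    the number of dropped replicates.
    """
    if n_replicates < 1:
        raise BarcodeError("n_replicates must be >= 1")
    if block not in (1, 3):
        raise BarcodeError("block must be 1 (columns) or 3 (codons)")
    codes = encode_alignment(r.sequence for r in dataset.records)
    if tree is None:
        tree = nj_build(distance_matrix(dataset))
    orig_bip = tree.bipartitions()
    counts = {bp: 0 for bp in orig_bip}
    ids = dataset.ids
    ref_mat = DistanceMatrix(ids, np.zeros((len(ids), len(ids))),
                             np.zeros((len(ids), len(ids)), dtype=int),
                             np.ones((len(ids), len(ids)), dtype=bool))

    rng = np.random.default_rng(seed)
    L = dataset.alignment_length
    dropped = 0
    for _ in range(n_replicates):
        if block == 1:
            cols = rng.integers(0, L, size=L)
        else:
            starts = np.arange(dataset.codon_offset, L - 2, 3)
            pick = rng.integers(0, len(starts), size=len(starts))
            cols = (starts[pick][:, None] + np.arange(3)).ravel()
        d, _, defined = k2p_matrix_from_codes(codes[:, cols])
        if not defined.all():
            dropped += 1
            continue
        rep_mat = DistanceMatrix(ids, d, ref_mat.n_comparable, defined)
        rep_tree = nj_build(rep_mat)
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    n_valid = n_replicates - dropped
    if dropped > 0.1 * n_replicates or n_valid == 0:
        raise BootstrapError(
            f"{dropped}/{n_replicates} bootstrap replicates dropped for "
            "saturated distances"
        )
    for bp, node in orig_bip.items():
        node.support = 100.0 * counts[bp] / n_valid
    if dropped:
        logger.warning("bootstrap: %d/%d replicates dropped", dropped,
                       n_replicates)
    return tree, dropped


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

def assess_monophyly(tree: PhyloTree,
                     taxonomy: dict[str, tuple[str, str, str, str]],
                     ) -> list[MonophylyRecord]:
    """Unrooted monophyly per species: its individuals must be exactly one
    side of some branch.  Singleton species are trivially monophyletic."""
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in taxonomy]
    if missing:
        raise BarcodeError(f"taxonomy missing for tree leaves {missing[:5]}")
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    bip = tree.bipartitions()

    by_species: dict[str, set[str]] = {}
    for leaf in leaves:
        by_species.setdefault(taxonomy[leaf][0], set()).add(leaf)

    records = []
    for sp in sorted(by_species):
        members = frozenset(by_species[sp])
        if len(members) == 1:
            records.append(MonophylyRecord(sp, 1, True, None))
            continue
        if members == all_leaves:
            records.append(MonophylyRecord(sp, len(members), True, None))
            continue
        canon = all_leaves - members if ref in members else members
        complement = all_leaves - members
        if len(complement) == 1:
            # species = all but one leaf: the defining branch is the
            # remaining leaf's pendant edge, always present
            records.append(MonophylyRecord(sp, len(members), True, None))
            continue
        node = bip.get(canon)
        records.append(MonophylyRecord(
            sp, len(members), node is not None,
            node.support if node is not None else None,
        ))
    return records


# ---------------------------------------------------------------------------
# Newick serialisation
# ---------------------------------------------------------------------------

def _sanitize(name: str, quote: bool) -> str:
    specials = set(" \t():;,'[]")
    if not specials & set(name):
        return name
    if quote:
        return "'" + name.replace("'", "''") + "'"
    return name.translate(str.maketrans({c: "_" for c in specials}))


def to_newick(tree: PhyloTree, quote_names: bool = False) -> str:
    """Serialise with 6-significant-digit branch lengths, integer supports
    as internal labels, and children ordered by smallest leaf name."""

    def fmt(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf:
            s = _sanitize(node.name, quote_names)
        else:
            kids = sorted(node.children, key=lambda ch: min(ch.leaf_names()))
            s = "(" + ",".join(fmt(ch, True) for ch in kids) + ")"
            if node.support is not None:
                s += str(round(node.support))
        if with_length:
            s += f":{node.length:.6g}"
        return s

    return fmt(tree.root, False) + ";"


def from_newick(text: str) -> PhyloTree:
    """Parse a Newick string (labels, branch lengths, internal support
    labels, single-quoted names)."""
    text = text.strip()
    if not text.endswith(";"):
        raise BarcodeError("Newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise BarcodeError(f"Newick parse error at {pos}")
        label = _parse_label()
        if label:
            if node.children:
                node.support = float(label)
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            node.length = float(s[start:pos])
        return node

    def _parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in ":,();":
            pos += 1
        return s[start:pos]

    root = parse_node()
    if pos != len(s):
        raise BarcodeError(f"trailing characters in Newick string at {pos}")
    return PhyloTree(root)
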