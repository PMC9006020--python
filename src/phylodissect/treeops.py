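"""Unrooted phylogenetic trees, bipartition algebra and support bookkeeping.

Trees are held as undirected adjacency maps with branch lengths on edges;
Newick parsing is delegated to dendropy, writing is a small deterministic
emitter that preserves labels and branch lengths to 10 significant digits.
A bipartition is the two-way leaf split induced by an internal edge, stored
in a canonical (smaller-side) form so that a split and its complement
compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import dendropy


class TreeError(ValueError):
    """Invalid tree input or operation."""


class PhyloTree:
    """Unrooted tree with branch lengths, binary internally unless built otherwise.

    Nodes are integers; leaves carry labels.  The adjacency map preserves
    insertion order, which makes copies and Newick output deterministic.
    """

    def __init__(self):
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}  # leaf node -> taxon label
        self.node_labels: dict[int, str] = {}  # internal node annotations (e.g. support)
        self._next = 0

    # -- construction ---------------------------------------------------

    def add_node(self, label: Optional[str] = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0 or not (length == length):
            raise TreeError(f"branch length must be finite and >= 0, got {length}")
        self.adj[u][v] = float(length)
        self.adj[v][u] = float(length)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise TreeError(f"cannot parse Newick: {exc}") from exc
        tree = cls()
        node_map: dict = {}
        for node in dt.preorder_node_iter():
            label = None
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if label is None:
                    raise TreeError("leaf without a label in Newick input")
            nid = tree.add_node(label)
            if not node.is_leaf() and node.label:
                tree.node_labels[nid] = node.label
            node_map[node] = nid
            if node.parent_node is not None:
                length = node.edge.length if node.edge.length is not None else 0.0
                tree.add_edge(node_map[node.parent_node], nid, length)
        labels = list(tree.labels.values())
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels in Newick input")
        tree._suppress_degree_two()
        return tree

    def _suppress_degree_two(self) -> None:
        """Remove degree-2 nodes (e.g. a rooted Newick's root), merging lengths."""
        for node in list(self.adj):
            if node in self.labels:
                continue
            while node in self.adj and len(self.adj[node]) == 2:
                (a, ta), (b, tb) = self.adj[node].items()
                del self.adj[a][node]
                del self.adj[b][node]
                del self.adj[node]
                self.node_labels.pop(node, None)
                self.adj[a][b] = ta + tb
                self.adj[b][a] = ta + tb
                break

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.adj = {u: dict(nbrs) for u, nbrs in self.adj.items()}
        t.labels = dict(self.labels)
        t.node_labels = dict(self.node_labels)
        t._next = self._next
        return t

    # -- basic queries ---------------------------------------------------

    @property
    def leaves(self) -> list[int]:
        return [n for n in self.adj if n in self.labels]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[n] for n in self.leaves]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_of(self, label: str) -> int:
        for n, lab in self.labels.items():
            if lab == label:
                return n
        raise TreeError(f"no leaf labelled {label!r}")

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for (u, v) in self.edges()
            if u not in self.labels and v not in self.labels
        ]

    def length(self, u: int, v: int) -> float:
        return self.adj[u][v]

    def set_length(self, u: int, v: int, t: float) -> None:
        if t < 0 or not (t == t):
            raise TreeError(f"branch length must be finite and >= 0, got {t}")
        self.adj[u][v] = float(t)
        self.adj[v][u] = float(t)

    def total_length(self) -> float:
        return sum(self.adj[u][v] for u, v in self.edges())

    # -- traversal -------------------------------------------------------

    def postorder(self, root: int) -> list[tuple[int, Optional[int]]]:
        """(node, parent) pairs, children before parents, rooted at `root`."""
        order: list[tuple[int, Optional[int]]] = []
        stack = [(root, None)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nbr in self.adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        order.reverse()
        return order

    def side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Labels of leaves on the `v` side of edge (u, v)."""
        seen = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node in self.labels:
                seen.add(self.labels[node])
            for nbr in self.adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        return frozenset(seen)

    # -- rearrangement ---------------------------------------------------

    def nni_neighbors(self, u: int, v: int) -> list["PhyloTree"]:
        """The two nearest-neighbour-interchange trees around internal edge (u, v)."""
        if u in self.labels or v in self.labels:
            raise TreeError("NNI requires an internal edge")
        u_nbrs = [n for n in self.adj[u] if n != v]
        v_nbrs = [n for n in self.adj[v] if n != u]
        if len(u_nbrs) != 2 or len(v_nbrs) != 2:
            raise TreeError("NNI requires a binary internal edge")
        out = []
        b = u_nbrs[1]
        for c in v_nbrs:
            t = self.copy()
            tb, tc = t.adj[u][b], t.adj[v][c]
            del t.adj[u][b], t.adj[b][u], t.adj[v][c], t.adj[c][v]
            t.adj[u][c] = tc
            t.adj[c][u] = tc
            t.adj[v][b] = tb
            t.adj[b][v] = tb
            out.append(t)
        return out

    # -- Newick ----------------------------------------------------------

    def to_newick(self, include_node_labels: bool = True) -> str:
        if self.n_leaves == 0:
            raise TreeError("cannot write an empty tree")
        if self.n_leaves == 1:
            (leaf,) = self.leaves
            return f"{self.labels[leaf]};"
        anchor = min(self.leaves, key=lambda n: self.labels[n])
        root = next(iter(self.adj[anchor]))

        def emit(node: int, parent: Optional[int]) -> str:
            children = [n for n in self.adj[node] if n != parent]
            if not children:
                name = self.labels[node]
            else:
                inner = ",".join(emit(c, node) for c in children)
                lab = self.node_labels.get(node, "") if include_node_labels else ""
                name = f"({inner}){lab}"
            if parent is None:
                return name
            return f"{name}:{self.adj[parent][node]:.10g}"

        return emit(root, None) + ";"

    def __repr__(self):
        return f"PhyloTree({self.n_leaves} leaves)"


@dataclass(frozen=True)
class Bipartition:
    """Canonical two-way split of a taxon set induced by an internal edge.

    `side` is the smaller half (ties broken lexicographically), so a split
    and its complement canonicalize identically.
    """

    side: frozenset[str]
    taxa: frozenset[str]

    @classmethod
    def make(cls, side: Iterable[str], taxa: Iterable[str]) -> "Bipartition":
        taxa = frozenset(taxa)
        side = frozenset(side)
        other = taxa - side
        if not side or not other:
            raise TreeError("a bipartition needs two non-empty sides")
        if len(side) > len(other) or (
            len(side) == len(other) and sorted(side) > sorted(other)
        ):
            side = other
        return cls(side=side, taxa=taxa)

    @property
    def complement(self) -> frozenset[str]:
        return self.taxa - self.side


def bipartition_set(tree: PhyloTree) -> set[Bipartition]:
    """One bipartition per internal edge; n-3 entries for a binary tree."""
    taxa = frozenset(tree.labels.values())
    if len(taxa) < 4:
        raise TreeError("bipartitions require >= 4 taxa")
    out = set()
    for u, v in tree.internal_edges():
        out.add(Bipartition.make(tree.side_leaves(u, v), taxa))
    return out


def restricted_bipartitions(
    tree: PhyloTree, restrict: frozenset[str]
) -> set[Bipartition]:
    """Bipartitions of the tree restricted to a taxon subset.

    Each side is intersected with `restrict`; splits that become trivial
    (a side with fewer than 2 members) are dropped.
    """
    out = set()
    for u, v in tree.internal_edges():
        side = tree.side_leaves(u, v) & restrict
        other = restrict - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(Bipartition.make(side, restrict))
    return out


def clade_support(
    trees: Sequence[PhyloTree],
    clade: Iterable[str],
    restrict: Optional[Iterable[str]] = None,
) -> float:
    """Percentage of trees containing the clade's bipartition.

    When `restrict` is given, every tree's bipartitions are first
    restricted to that taxon subset, which makes support comparable across
    taxon-deletion schemes.  Complement-invariant by canonicalization.
    """
    if not trees:
        raise TreeError("clade_support needs at least one tree")
    clade = frozenset(clade)
    universe = (
        frozenset(restrict) if restrict is not None else frozenset(trees[0].labels.values())
    )
    clade = clade & universe
    if len(clade) < 2 or len(universe - clade) < 2:
        raise TreeError(
            "clade and its complement must each have >= 2 taxa after restriction"
        )
    target = Bipartition.make(clade, universe)
    hits = 0
    for t in trees:
        tree_taxa = frozenset(t.labels.values())
        bips = (
            restricted_bipartitions(t, universe)
            if universe != tree_taxa
            else bipartition_set(t)
        )
        if target in bips:
            hits += 1
    return 100.0 * hits / len(trees)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference bipartition distance between two trees."""
    s1 = frozenset(t1.labels.values())
    s2 = frozenset(t2.labels.values())
    if s1 != s2:
        raise TreeError("Robinson-Foulds distance requires identical leaf sets")
    return len(bipartition_set(t1) ^ bipartition_set(t2))


def restrict_tree(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Prune the tree to a taxon subset, merging path lengths through
    removed degree-2 nodes."""
    keep = set(keep)
    missing = keep - set(tree.labels.values())
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(t.adj):
            if node in t.labels and t.labels[node] not in keep:
                (nbr,) = t.adj[node]
                del t.adj[nbr][node]
                del t.adj[node]
                del t.labels[node]
                changed = True
        for node in list(t.adj):
            if node not in t.labels and len(t.adj[node]) <= 2:
                if len(t.adj[node]) == 2:
                    (a, ta), (b, tb) = t.adj[node].items()
                    del t.adj[a][node], t.adj[b][node], t.adj[node]
                    t.node_labels.pop(node, None)
                    t.adj[a][b] = ta + tb
                    t.adj[b][a] = ta + tb
                elif len(t.adj[node]) == 1:
                    (nbr,) = t.adj[node]
                    del t.adj[nbr][node]
                    del t.adj[node]
                    t.node_labels.pop(node, None)
                else:
                    del t.adj[node]
                changed = True
    return t
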