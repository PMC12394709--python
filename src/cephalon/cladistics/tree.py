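"""Phylogenetic tree container with split (bipartition) machinery.

Trees are stored as an undirected adjacency map with optional branch
lengths.  Leaves carry taxon names; internal nodes are anonymous.  The same
container serves unrooted parsimony trees (internal degree 3, or polytomies
in consensus trees) and rooted display/likelihood trees (the ``root``
attribute marks the rooting, which never affects parsimony or reversible
likelihood scores).

Splits are encoded as integer bitmasks over a fixed taxon order and
normalised to exclude the first taxon, so two trees on the same taxon set
compare split-for-split regardless of rooting.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "random_binary_tree",
    "enumerate_topologies",
    "strict_consensus",
    "rf_distance",
    "tree_from_splits",
]


class Tree:
    """Undirected phylogenetic tree over named leaves.

    Parameters
    ----------
    adj:
        ``{node: {neighbor: branch_length_or_None}}``; must be symmetric.
    names:
        ``{leaf_node: taxon_name}``.
    root:
        Optional node id marking a rooting for display/likelihood.
    """

    __slots__ = ("adj", "names", "root")

    def __init__(self, adj: dict, names: dict, root: int | None = None):
        self.adj = {u: dict(nbrs) for u, nbrs in adj.items()}
        self.names = dict(names)
        self.root = root

    # -- basic structure ---------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return sorted(self.names.values())

    @property
    def n_leaves(self) -> int:
        return len(self.names)

    def leaves(self) -> list[int]:
        return sorted(self.names)

    def copy(self) -> "Tree":
        return Tree(self.adj, self.names, self.root)

    def is_binary_unrooted(self) -> bool:
        return all(
            len(nbrs) in (1, 3) for nbrs in self.adj.values()
        ) and all(len(self.adj[u]) == 1 for u in self.names)

    def postorder(self, root: int | None = None) -> list[tuple[int, int | None]]:
        """(node, parent) pairs, children before parents."""
        if root is None:
            root = self.root
        if root is None:  # any internal node, or the single edge's endpoint
            root = next((u for u in self.adj if u not in self.names), next(iter(self.adj)))
        order: list[tuple[int, int | None]] = []
        stack: list[tuple[int, int | None]] = [(root, None)]
        while stack:
            u, p = stack.pop()
            order.append((u, p))
            for v in self.adj[u]:
                if v != p:
                    stack.append((v, u))
        order.reverse()
        return order

    # -- splits ------------------------------------------------------------

    def splits(self, taxon_order: Sequence[str] | None = None) -> frozenset[int]:
        """Nontrivial splits as normalised bitmasks over ``taxon_order``."""
        if taxon_order is None:
            taxon_order = self.taxa
        bit = {name: 1 << i for i, name in enumerate(taxon_order)}
        n = len(taxon_order)
        full = (1 << n) - 1
        masks: dict[int, int] = {}
        out: set[int] = set()
        for u, p in self.postorder():
            if u in self.names:
                masks[u] = bit[self.names[u]]
            else:
                masks[u] = 0
                for v in self.adj[u]:
                    if v != p:
                        masks[u] |= masks[v]
            if p is not None:
                m = masks[u]
                if m & 1:
                    m = full ^ m
                if 2 <= m.bit_count() <= n - 2:
                    out.add(m)
        return frozenset(out)

    def topology_key(self, taxon_order: Sequence[str] | None = None) -> frozenset[int]:
        """Canonical identifier of the unrooted topology."""
        return self.splits(taxon_order)

    # -- newick ------------------------------------------------------------

    def to_newick(self, include_lengths: bool = True) -> str:
        root = self.root
        if root is None:
            root = next((u for u in self.adj if u not in self.names), next(iter(self.adj)))

        def label(u: int) -> str:
            return self.names.get(u, "")

        def fmt(u: int, p: int | None) -> str:
            kids = sorted(
                (v for v in self.adj[u] if v != p),
                key=lambda v: min_taxon[v],
            )
            if not kids:
                s = label(u)
            else:
                s = "(" + ",".join(fmt(v, u) for v in kids) + ")" + label(u)
            if p is not None and include_lengths and self.adj[u][p] is not None:
                s += f":{self.adj[u][p]:.10g}"
            return s

        # deterministic child ordering keyed by smallest taxon name below
        min_taxon: dict[int, str] = {}
        for u, p in self.postorder(root):
            if u in self.names:
                min_taxon[u] = self.names[u]
            else:
                min_taxon[u] = min(
                    (min_taxon[v] for v in self.adj[u] if v != p), default="~"
                )
        return fmt(root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = True) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(dt, rooted=rooted)

    @classmethod
    def from_dendropy(cls, dt: "dendropy.Tree", rooted: bool = True) -> "Tree":
        adj: dict[int, dict[int, float | None]] = {}
        names: dict[int, str] = {}
        ids: dict = {}

        def nid(nd) -> int:
            if nd not in ids:
                ids[nd] = len(ids)
                adj[ids[nd]] = {}
            return ids[nd]

        for edge in dt.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = nid(edge.tail_node), nid(edge.head_node)
            adj[u][v] = edge.length
            adj[v][u] = edge.length
        for leaf in dt.leaf_node_iter():
            names[nid(leaf)] = leaf.taxon.label
        root = nid(dt.seed_node)
        # suppress a degree-2 seed node when the tree is meant unrooted
        if not rooted and len(adj[root]) == 2:
            (a, la), (b, lb) = adj[root].items()
            length = None
            if la is not None or lb is not None:
                length = (la or 0.0) + (lb or 0.0)
            del adj[a][root], adj[b][root], adj[root]
            adj[a][b] = adj[b][a] = length
            root = None
        return cls(adj, names, root if rooted else None)

    def to_dendropy(self, taxon_namespace=None) -> "dendropy.Tree":
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_leaves={self.n_leaves})"


# -- constructors ----------------------------------------------------------


def _three_leaf(taxa: Sequence[str]) -> tuple[dict, dict, int]:
    """Unrooted star on the first three taxa; returns (adj, names, next_id)."""
    adj = {0: {3: None}, 1: {3: None}, 2: {3: None}, 3: {0: None, 1: None, 2: None}}
    names = {i: taxa[i] for i in range(3)}
    return adj, names, 4


def _insert_leaf(adj: dict, leaf: int, u: int, v: int, internal: int) -> None:
    """Attach ``leaf`` on edge (u, v) via new node ``internal`` (in place)."""
    del adj[u][v], adj[v][u]
    adj[internal] = {u: None, v: None, leaf: None}
    adj[u][internal] = adj[v][internal] = None
    adj[leaf] = {internal: None}


def random_binary_tree(
    taxa: Sequence[str],
    rng: np.random.Generator,
    branch_length: float | None = None,
) -> Tree:
    """Uniform-addition random unrooted binary tree, optional equal lengths."""
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    order = list(rng.permutation(len(taxa)))
    taxa_perm = [taxa[i] for i in order]
    adj, names, nxt = _three_leaf(taxa_perm)
    for k in range(3, len(taxa_perm)):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        leaf = nxt
        _insert_leaf(adj, leaf, u, v, nxt + 1)
        names[leaf] = taxa_perm[k]
        nxt += 2
    if branch_length is not None:
        adj = {
            u: {v: branch_length for v in nbrs} for u, nbrs in adj.items()
        }
    return Tree(adj, names)


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[Tree]:
    """All (2n-5)!! distinct unrooted binary topologies; n <= 9 enforced."""
    n = len(taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if n > 9:
        raise ValueError("exhaustive enumeration limited to 9 taxa")

    def rec(adj: dict, names: dict, nxt: int, k: int) -> Iterator[tuple[dict, dict]]:
        if k == n:
            yield adj, names
            return
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for u, v in edges:
            a2 = {x: dict(nb) for x, nb in adj.items()}
            _insert_leaf(a2, nxt, u, v, nxt + 1)
            n2 = dict(names)
            n2[nxt] = taxa[k]
            yield from rec(a2, n2, nxt + 2, k + 1)

    adj0, names0, nxt0 = _three_leaf(taxa)
    for adj, names in rec(adj0, names0, nxt0, 3):
        yield Tree(adj, names)


# -- consensus / comparison -------------------------------------------------


def tree_from_splits(
    splits: Iterable[int], taxon_order: Sequence[str]
) -> Tree:
    """Build the (possibly multifurcating) tree displaying exactly ``splits``.

    Splits must be pairwise compatible bitmasks normalised to exclude bit 0.
    """
    n = len(taxon_order)
    names = {i: taxon_order[i] for i in range(n)}
    root = n
    parent = {i: root for i in range(n)}
    children: dict[int, set[int]] = {root: set(range(n))}
    mask = {i: 1 << i for i in range(n)}
    nxt = n + 1
    for s in sorted(set(splits), key=lambda m: m.bit_count()):
        # under compatibility, processing small->large guarantees the cluster
        # roots inside s are siblings under a single host node
        host = members = None
        for p, kids in children.items():
            inside = {c for c in kids if mask[c] & s == mask[c]}
            if inside and _mask_union(mask, inside) == s:
                host, members = p, inside
                break
        if host is None:
            raise ValueError(f"incompatible split {s:b}")
        u = nxt
        nxt += 1
        children[host] -= members
        children[host].add(u)
        children[u] = members
        mask[u] = s
        parent[u] = host
        for c in members:
            parent[c] = u
    adj: dict[int, dict[int, float | None]] = {u: {} for u in mask}
    adj.setdefault(root, {})
    for c, p in parent.items():
        adj[c][p] = None
        adj.setdefault(p, {})[c] = None
    # suppress a degree-2 root
    if len(adj[root]) == 2:
        a, b = adj[root]
        del adj[a][root], adj[b][root], adj[root]
        adj[a][b] = adj[b][a] = None
    return Tree(adj, names)


def _mask_union(mask: dict, nodes: set[int]) -> int:
    m = 0
    for c in nodes:
        m |= mask[c]
    return m


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree whose splits are exactly those shared by every input tree."""
    if not trees:
        raise ValueError("need >= 1 tree")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise ValueError("trees must share an identical leaf set")
    common = trees[0].splits(taxa)
    for t in trees[1:]:
        common &= t.splits(taxa)
    return tree_from_splits(common, taxa)


def rf_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds distance (symmetric difference of split sets)."""
    if a.taxa != b.taxa:
        raise ValueError("trees must share an identical leaf set")
    order = a.taxa
    return len(a.splits(order) ^ b.splits(order))
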