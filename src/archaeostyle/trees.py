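"""Unrooted tree structure for parsimony search and consensus.

Trees are stored as adjacency maps over integer node ids; leaves are ids
``0..n-1`` and coincide with taxon indices, internal nodes are ``>= n``.
Bipartitions are bitmask integers over taxon indices, normalised to the
side *not* containing taxon 0, which makes hashing, Robinson--Foulds
distances and consensus operations cheap set algebra.
"""
from __future__ import annotations

from typing import Iterable, Iterator, Sequence

from .errors import InvalidInputError, LeafSetMismatchError


class UnrootedTree:
    """Unrooted (binary or multifurcating) tree over taxa 0..n-1."""

    __slots__ = ("n_taxa", "adj", "_next_id")

    def __init__(self, n_taxa: int, adj: dict[int, set[int]] | None = None):
        if n_taxa < 3:
            raise InvalidInputError("need at least 3 taxa for an unrooted tree")
        self.n_taxa = n_taxa
        if adj is None:
            # the unique unrooted topology on the first 3 taxa
            hub = n_taxa
            adj = {hub: {0, 1, 2}, 0: {hub}, 1: {hub}, 2: {hub}}
        self.adj = adj
        self._next_id = max(adj) + 1

    # -- construction ---------------------------------------------------
    def copy(self) -> "UnrootedTree":
        t = UnrootedTree.__new__(UnrootedTree)
        t.n_taxa = self.n_taxa
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t._next_id = self._next_id
        return t

    def _new_node(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def attach_leaf(self, leaf: int, edge: tuple[int, int]) -> None:
        """Insert ``leaf`` by subdividing ``edge`` with a new internal node."""
        u, v = edge
        if v not in self.adj[u]:
            raise InvalidInputError(f"({u}, {v}) is not an edge")
        mid = self._new_node()
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.adj[mid] = {u, v, leaf}
        self.adj[u].add(mid)
        self.adj[v].add(mid)
        self.adj[leaf] = {mid}

    # -- traversal ------------------------------------------------------
    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u < v:
                    out.append((u, v))
        return out

    def postorder(self, root: int = 0) -> list[tuple[int, int]]:
        """(node, parent) pairs, children before parents, rooted at ``root``."""
        order: list[tuple[int, int]] = []
        stack = [(root, -1)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for nbr in self.adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        order.reverse()
        return order

    def is_binary(self) -> bool:
        return all(
            len(nbrs) == (1 if node < self.n_taxa else 3)
            for node, nbrs in self.adj.items()
        )

    # -- bipartitions ---------------------------------------------------
    def bipartitions(self) -> frozenset[int]:
        """Non-trivial bipartitions as bitmasks excluding taxon 0's side."""
        n = self.n_taxa
        full = (1 << n) - 1
        below: dict[int, int] = {}
        masks = []
        for node, parent in self.postorder(0):
            if node < n:
                below[node] = 1 << node
            else:
                m = 0
                for nbr in self.adj[node]:
                    if nbr != parent:
                        m |= below[nbr]
                below[node] = m
            if parent != -1:
                mask = below[node]
                if mask & 1:
                    mask ^= full
                if 2 <= bin(mask).count("1") <= n - 2:
                    masks.append(mask)
        return frozenset(masks)

    def topology_key(self) -> frozenset[int]:
        """Canonical identity of the (strictly bifurcating) topology."""
        return self.bipartitions()

    def contains_clade(self, mask: int) -> bool:
        full = (1 << self.n_taxa) - 1
        if mask & 1:
            mask ^= full
        return mask in self.bipartitions()

    def rf_distance(self, other: "UnrootedTree") -> int:
        if self.n_taxa != other.n_taxa:
            raise LeafSetMismatchError("trees have different leaf counts")
        return len(self.bipartitions() ^ other.bipartitions())

    # -- SPR ------------------------------------------------------------
    def _component(self, start: int, banned: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v != banned and v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    def spr_neighbours(self) -> Iterator["UnrootedTree"]:
        """All trees one subtree-prune-and-regraft move away (binary trees)."""
        for u, v in list(self.edges()):
            # prune the subtree rooted at v (cut edge u-v); u must be internal
            for cut_keep, cut_move in ((u, v), (v, u)):
                if cut_keep < self.n_taxa:
                    continue  # cannot smooth a leaf
                rest = self._component(cut_keep, banned=cut_move)
                a, b = [x for x in self.adj[cut_keep] if x != cut_move]
                for e1, e2 in self._edges_within(rest, exclude=cut_keep):
                    if {e1, e2} == {a, b}:
                        continue  # reattaching where it came from
                    t = self.copy()
                    # smooth out cut_keep
                    t.adj[a].discard(cut_keep)
                    t.adj[b].discard(cut_keep)
                    t.adj[a].add(b)
                    t.adj[b].add(a)
                    nbrs = t.adj.pop(cut_keep)
                    # re-use cut_keep as the new attachment node
                    t.adj[e1].discard(e2)
                    t.adj[e2].discard(e1)
                    t.adj[cut_keep] = {e1, e2, cut_move}
                    t.adj[e1].add(cut_keep)
                    t.adj[e2].add(cut_keep)
                    t.adj[cut_move].discard(cut_keep)
                    t.adj[cut_move].add(cut_keep)
                    yield t

    def _edges_within(self, nodes: set[int], exclude: int) -> list[tuple[int, int]]:
        out = []
        for u in nodes:
            if u == exclude:
                continue
            for v in self.adj[u]:
                if u < v and v != exclude and v in nodes:
                    out.append((u, v))
        return out

    # -- newick ---------------------------------------------------------
    def to_newick(self, taxa: Sequence[str] | None = None,
                  support: dict[int, float] | None = None) -> str:
        """Newick string rooted arbitrarily at taxon 0's neighbour.

        ``support`` maps bipartition masks to node labels (e.g. bootstrap %).
        """
        names = taxa or [f"T{i}" for i in range(self.n_taxa)]
        full = (1 << self.n_taxa) - 1
        below: dict[int, int] = {}
        for node, parent in self.postorder(0):
            if node < self.n_taxa:
                below[node] = 1 << node
            else:
                below[node] = 0
                for nbr in self.adj[node]:
                    if nbr != parent:
                        below[node] |= below[nbr]

        def label(node: int, parent: int) -> str:
            if support is None or node < self.n_taxa:
                return ""
            mask = below[node]
            if mask & 1:
                mask ^= full
            if mask in support:
                return format(support[mask], "g")
            return ""

        def render(node: int, parent: int) -> str:
            if node < self.n_taxa:
                return names[node]
            parts = [render(c, node) for c in self.adj[node] if c != parent]
            return "(" + ",".join(parts) + ")" + label(node, parent)

        root = next(iter(self.adj[0]))
        inner = [render(c, root) for c in self.adj[root] if c != 0]
        return "(" + names[0] + "," + ",".join(inner) + ");"

    @classmethod
    def from_newick(cls, newick: str, taxa: Sequence[str]) -> "UnrootedTree":
        """Parse a newick string over the given taxon names (topology only)."""
        import dendropy

        tns = dendropy.TaxonNamespace([str(t) for t in taxa])
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 taxon_namespace=tns, preserve_underscores=True)
        tree.encode_bipartitions()
        index = {str(t): i for i, t in enumerate(taxa)}
        n = len(taxa)
        t = cls(n)
        # rebuild adjacency from the dendropy structure (unroot by suppressing
        # the root if it has degree 2)
        tree.deroot()
        node_ids: dict = {}
        next_id = [n]

        def nid(nd):
            if nd not in node_ids:
                if nd.is_leaf():
                    node_ids[nd] = index[nd.taxon.label]
                else:
                    node_ids[nd] = next_id[0]
                    next_id[0] += 1
            return node_ids[nd]

        adj: dict[int, set[int]] = {}
        for edge in tree.preorder_edge_iter():
            if edge.head_node is None or edge.tail_node is None:
                continue
            a, b = nid(edge.tail_node), nid(edge.head_node)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        t.adj = adj
        t._next_id = max(adj) + 1
        return t


# ---------------------------------------------------------------------------
# Enumeration and construction helpers
# ---------------------------------------------------------------------------

def all_topologies(n_taxa: int) -> Iterator[UnrootedTree]:
    """Every unrooted binary topology, by recursive leaf insertion.

    There are (2n-5)!! of them; usable up to ~9 taxa.
    """
    if n_taxa < 3:
        raise InvalidInputError("need at least 3 taxa")

    def grow(tree: UnrootedTree, leaf: int) -> Iterator[UnrootedTree]:
        if leaf == n_taxa:
            yield tree
            return
        for edge in tree.edges():
            t = tree.copy()
            t.attach_leaf(leaf, edge)
            yield from grow(t, leaf + 1)

    base = UnrootedTree(n_taxa)
    yield from grow(base, 3)


def tree_from_bipartitions(n_taxa: int, masks: Iterable[int]) -> UnrootedTree:
    """Build the (possibly multifurcating) tree displaying a compatible set
    of bipartitions, all normalised away from taxon 0."""
    full = (1 << n_taxa) - 1
    masks = sorted({m ^ full if m & 1 else m for m in masks}, key=lambda m: -bin(m).count("1"))
    tree = UnrootedTree.__new__(UnrootedTree)
    tree.n_taxa = n_taxa
    root = n_taxa
    adj: dict[int, set[int]] = {root: set()}
    tree.adj = adj
    tree._next_id = n_taxa + 1
    # rooted-at-taxon-0 cluster tree: every mask is a cluster of the rooted tree
    parent_of_cluster: dict[int, int] = {}

    def place(mask: int, node_mask_pairs: list[tuple[int, int]]) -> int:
        # find the smallest existing cluster strictly containing mask
        best, best_node = full, root
        for m, nd in node_mask_pairs:
            if m != mask and (mask & ~m) == 0 and bin(m).count("1") < bin(best).count("1"):
                best, best_node = m, nd
        return best_node

    placed: list[tuple[int, int]] = []
    for mask in masks:
        node = tree._next_id
        tree._next_id += 1
        parent = place(mask, placed)
        adj.setdefault(parent, set()).add(node)
        adj[node] = {parent}
        placed.append((mask, node))
    # attach leaves
    adj.setdefault(root, set()).add(0)
    adj[0] = {root}
    for leaf in range(1, n_taxa):
        bit = 1 << leaf
        parent = place(bit, placed)
        adj.setdefault(parent, set()).add(leaf)
        adj[leaf] = {parent}
    # suppress any degree-2 internal nodes (can arise if root got one child)
    for node in [n for n in list(adj) if n >= n_taxa]:
        if len(adj[node]) == 2:
            a, b = adj.pop(node)
            adj[a].discard(node)
            adj[b].discard(node)
            adj[a].add(b)
            adj[b].add(a)
    return tree


def strict_consensus(trees: Sequence[UnrootedTree]) -> UnrootedTree:
    """Tree containing exactly the bipartitions shared by every input."""
    if not trees:
        raise InvalidInputError("need at least one tree")
    n = trees[0].n_taxa
    if any(t.n_taxa != n for t in trees):
        raise LeafSetMismatchError("all trees must share one leaf set")
    common = frozenset.intersection(*(t.bipartitions() for t in trees))
    return tree_from_bipartitions(n, common)


# ---------------------------------------------------------------------------
# Adams consensus (rooted)
# ---------------------------------------------------------------------------
# Rooted trees are nested tuples: a leaf is an int, an internal node a tuple
# of two or more subtrees.

def root_at_taxon(tree: UnrootedTree, outgroup: int = 0):
    """Nested-tuple rooted tree: root has the outgroup leaf and the ingroup."""

    def build(node: int, parent: int):
        if node < tree.n_taxa:
            return node
        return tuple(build(c, node) for c in tree.adj[node] if c != parent)

    hub = next(iter(tree.adj[outgroup]))
    return (outgroup, build(hub, outgroup))


def _leafset(t) -> frozenset[int]:
    if isinstance(t, int):
        return frozenset((t,))
    return frozenset().union(*(_leafset(c) for c in t))


def _restrict(t, keep: frozenset[int]):
    if isinstance(t, int):
        return t if t in keep else None
    kids = [r for r in (_restrict(c, keep) for c in t) if r is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def adams_consensus(rooted_trees: Sequence) -> tuple:
    """Adams (nesting) consensus of rooted trees on one leaf set.

    At each level the root partitions of all inputs are intersected (their
    common refinement); each block is restricted into every tree and the
    consensus recurses.  The result keeps exactly the nestings common to
    all inputs.
    """
    if len(rooted_trees) < 1:
        raise InvalidInputError("need at least one tree")
    leafsets = [_leafset(t) for t in rooted_trees]
    if len(set(leafsets)) != 1:
        raise LeafSetMismatchError("all trees must share one leaf set")

    def consensus(trees):
        first = trees[0]
        if isinstance(first, int):
            return first
        if all(isinstance(t, int) for t in trees):
            return first
        # partition product of root partitions
        leaves = _leafset(first)
        block_of: dict[int, tuple] = {}
        for leaf in leaves:
            key = []
            for t in trees:
                if isinstance(t, int):
                    key.append(0)
                    continue
                for i, child in enumerate(t):
                    if leaf in _leafset(child):
                        key.append(i)
                        break
            block_of[leaf] = tuple(key)
        blocks: dict[tuple, set[int]] = {}
        for leaf, key in block_of.items():
            blocks.setdefault(key, set()).add(leaf)
        if len(blocks) == 1:
            # all trees agree on a single block only if some tree is a leaf;
            # guard against infinite recursion by splitting on the first tree
            (block,) = blocks.values()
            subs = [_restrict(t, frozenset(block)) for t in trees]
            non_trivial = [s for s in subs if not isinstance(s, int)]
            if not non_trivial:
                return next(iter(block))
            # descend through the agreeing root
            return consensus([s if not isinstance(s, int) else s for s in subs])
        kids = []
        for block in blocks.values():
            keep = frozenset(block)
            kids.append(consensus([_restrict(t, keep) for t in trees]))
        return tuple(sorted(kids, key=lambda k: min(_leafset(k))))

    return consensus(list(rooted_trees))


def rooted_to_newick(t, taxa: Sequence[str]) -> str:
    def render(n):
        if isinstance(n, int):
            return str(taxa[n])
        return "(" + ",".join(render(c) for c in n) + ")"

    return render(t) + ";"


def nestings(t) -> set[tuple[frozenset[int], frozenset[int]]]:
    """All (A, B) pairs with A nested in B: A a cluster strictly inside
    another cluster B of the rooted tree."""
    clusters = []

    def walk(n):
        ls = _leafset(n)
        if not isinstance(n, int):
            clusters.append(ls)
            for c in n:
                walk(c)
        return ls

    walk(t)
    out = set()
    for a in clusters:
        for b in clusters:
            if a < b:
                out.add((a, b))
    return out
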