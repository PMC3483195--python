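"""Phylogenetic tree structures, Newick I/O, and LCA queries.

The species tree is the coordinate frame for every event count in the
analysis: births, deaths, duplications and deletions are all reported
against its branches.  A branch is identified by its *head* node (the node
the branch leads into), and internal nodes are named canonically by their
sorted leaf set joined with commas, so lineage labels are reproducible
across runs and match the packaged event-table fixture.

Newick parsing is delegated to :mod:`dendropy`; the parsed tree is
converted into a light parent/child node structure that the Dollo and
reconciliation traversals operate on directly.
"""

from __future__ import annotations

import importlib.resources
import io
from typing import Iterable, Iterator

import dendropy
import pandas as pd

__all__ = [
    "TreeError",
    "Node",
    "Tree",
    "UnrootedTree",
    "parse_newick",
    "write_newick",
    "species_tree",
    "table2_events",
    "METAZOAN_TAXA",
    "OUTGROUP_TAXA",
    "CLADES",
]

#: The nine metazoan taxa of the fixed species tree.
METAZOAN_TAXA = ("Hsa", "Mmu", "Gga", "Dme", "Aae", "Bmo", "Cel", "Cbr", "Tsp")

#: Outgroups: yeast and choanoflagellate.  Their branch lengths are
#: placeholders (1.0) and they are excluded from rate and index computations.
OUTGROUP_TAXA = ("Sce", "Mbr")

#: Clade membership of the metazoan taxa.
CLADES = {
    "vertebrates": frozenset({"Hsa", "Mmu", "Gga"}),
    "arthropods": frozenset({"Dme", "Aae", "Bmo"}),
    "nematodes": frozenset({"Cel", "Cbr", "Tsp"}),
}


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree queries."""


class Node:
    """A node of a rooted tree."""

    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.parent: "Node" | None = None
        self.children: list["Node"] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> tuple[str, ...]:
        return tuple(sorted(n.name for n in self.iter_leaves()))

    @property
    def canonical_name(self) -> str:
        """Leaf name for leaves; sorted leaf set joined by commas otherwise."""
        if self.is_leaf:
            return self.name
        return ",".join(self.leaf_names())

    def iter_leaves(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                yield n
            else:
                stack.extend(reversed(n.children))

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.canonical_name}>"


class Tree:
    """A rooted tree with unique leaf labels and optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._leaf_index: dict[str, Node] = {}
        for leaf in root.iter_leaves():
            if leaf.name is None:
                raise TreeError("unlabeled leaf")
            if leaf.name in self._leaf_index:
                raise TreeError(f"duplicate leaf label {leaf.name!r}")
            self._leaf_index[leaf.name] = leaf

    # -- basic queries ---------------------------------------------------
    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(sorted(self._leaf_index))

    def leaf(self, name: str) -> Node:
        try:
            return self._leaf_index[name]
        except KeyError:
            raise TreeError(f"unknown leaf label {name!r}") from None

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def branches(self) -> Iterator[Node]:
        """Every non-root node, i.e. every branch identified by its head."""
        for n in self.preorder():
            if n is not self.root:
                yield n

    def node_by_canonical(self, canonical: str) -> Node:
        for n in self.preorder():
            if n.canonical_name == canonical:
                return n
        raise TreeError(f"no node with canonical name {canonical!r}")

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder())

    # -- LCA -------------------------------------------------------------
    def lca(self, names: Iterable[str]) -> Node:
        """Deepest node ancestral to all given leaves."""
        names = list(names)
        if not names:
            raise TreeError("lca of an empty leaf set")
        nodes = [self.leaf(n) for n in names]
        # walk the first node's ancestor path, then lift the others onto it
        path = []
        n: Node | None = nodes[0]
        depth = {}
        while n is not None:
            depth[id(n)] = len(path)
            path.append(n)
            n = n.parent
        best = 0
        for other in nodes[1:]:
            m: Node | None = other
            while m is not None and id(m) not in depth:
                m = m.parent
            if m is None:  # pragma: no cover - cannot happen on one tree
                raise TreeError("disconnected leaves")
            best = max(best, depth[id(m)])
        return path[best]

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.length)
            for c in n.children:
                m.add_child(rec(c))
            return m

        return Tree(rec(self.root))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree {len(self._leaf_index)} leaves>"


class UnrootedTree:
    """An unrooted binary tree as an undirected adjacency structure.

    Produced by neighbor joining; consumed by the min-cost rooting search.
    Node ids are integers; leaves carry labels in :attr:`labels`.
    """

    def __init__(self):
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        i = self._next
        self._next += 1
        self.adj[i] = {}
        if label is not None:
            self.labels[i] = label
        return i

    def add_edge(self, u: int, v: int, length: float = 0.0) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u in sorted(self.adj):
            for v, w in self.adj[u].items():
                if u < v:
                    out.append((u, v, w))
        return out

    @property
    def leaves(self) -> list[int]:
        return [i for i in sorted(self.adj) if i in self.labels]

    def leaf_side(self, u: int, v: int) -> tuple[str, ...]:
        """Sorted labels of leaves on the *u* side of edge (u, v)."""
        seen = {v, u}
        out = []
        stack = [u]
        while stack:
            n = stack.pop()
            if n in self.labels:
                out.append(self.labels[n])
            for m in self.adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return tuple(sorted(out))

    def root_on_edge(self, u: int, v: int) -> Tree:
        """Root the tree on edge (u, v), splitting its length in half."""
        w = self.adj[u][v]

        def build(n: int, parent: int, length: float) -> Node:
            node = Node(self.labels.get(n), length)
            for m in sorted(self.adj[n]):
                if m != parent:
                    node.add_child(build(m, n, self.adj[n][m]))
            return node

        root = Node()
        root.add_child(build(u, v, w / 2.0))
        root.add_child(build(v, u, w / 2.0))
        return Tree(root)

    def rootings(self) -> Iterator[tuple[tuple[int, int], Tree]]:
        for u, v, _ in self.edges():
            yield (u, v), self.root_on_edge(u, v)

    def to_newick(self) -> str:
        """Serialize with a trifurcating base at an internal node (or the
        first leaf's neighbor for very small trees)."""
        internal = [n for n in sorted(self.adj) if n not in self.labels]
        base = internal[0] if internal else sorted(self.adj)[0]

        def rec(n: int, parent: int) -> str:
            kids = [m for m in sorted(self.adj[n]) if m != parent]
            if not kids:
                return f"{self.labels[n]}:{repr(float(self.adj[parent][n]))}"
            inner = ",".join(rec(m, n) for m in kids)
            length = "" if parent < 0 else f":{repr(float(self.adj[parent][n]))}"
            return f"({inner}){length}"

        return rec(base, -1) + ";"


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> Tree:
    """Parse a single Newick tree into a :class:`Tree`.

    Raises :class:`TreeError` on malformed input or duplicate leaf labels.
    """
    if not text.strip():
        raise TreeError("empty Newick string")
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dn) -> Node:
        name = None
        if dn.taxon is not None:
            name = dn.taxon.label
        elif dn.label:
            name = dn.label
        node = Node(name, dn.edge.length)
        for c in dn.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dt.seed_node)
    # internal labels are allowed in input but leaves must be labeled
    for leaf in root.iter_leaves():
        if not leaf.name:
            raise TreeError("leaf without a label")
    return Tree(root)


def _fmt_length(x: float) -> str:
    # shortest representation that round-trips the double exactly
    return repr(float(x))


def write_newick(tree: Tree) -> str:
    """Serialize a tree to Newick, preserving branch lengths exactly."""

    def rec(n: Node) -> str:
        if n.is_leaf:
            s = n.name
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")"
        if n.length is not None:
            s += ":" + _fmt_length(n.length)
        return s

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Packaged species-tree fixture


def _data_text(name: str) -> str:
    ref = importlib.resources.files("famdomevo.data").joinpath(name)
    return ref.read_text()


def species_tree() -> Tree:
    """The fixed 11-taxon species tree with the fixture branch lengths.

    The 17 metazoan branches carry the published lengths; the outgroup
    pendant branches (Sce, Mbr) and the stem into the metazoan crown carry
    placeholder length 1.0 and are excluded from rate computations.
    """
    return parse_newick(_data_text("species_tree.nwk"))


def table2_events() -> pd.DataFrame:
    """The packaged per-lineage event-count fixture (17 metazoan lineages).

    Columns: lineage (nested-paren label), canonical_name, branch_length,
    fam_birth, fam_death, dom_birth, dom_death, ufam_dup, ufam_del,
    udom_dup, udom_del.
    """
    df = pd.read_csv(io.StringIO(_data_text("table2_events.tsv")), sep="\t")
    return df
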