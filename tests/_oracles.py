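"""Independent brute-force oracles and random-structure generators.

Everything here is deliberately written against the *definitions* (set
intersections, exhaustive enumeration over scenarios) rather than the
algorithms used by the package, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import random

from famdomevo.trees import Node, Tree


# ---------------------------------------------------------------------------
# random / exhaustive tree generation


def random_rooted_tree(labels, rng: random.Random, with_lengths=True) -> Tree:
    """Random rooted binary tree by sequential leaf attachment."""
    labels = list(labels)
    rng.shuffle(labels)
    root = Node()
    root.add_child(Node(labels[0], rng.uniform(0.1, 2.0) if with_lengths else None))
    root.add_child(Node(labels[1], rng.uniform(0.1, 2.0) if with_lengths else None))
    leaves = list(root.children)
    for lab in labels[2:]:
        target = rng.choice(leaves)
        parent = target.parent
        inner = Node(None, rng.uniform(0.1, 2.0) if with_lengths else None)
        parent.children[parent.children.index(target)] = inner
        inner.parent = parent
        inner.add_child(target)
        new_leaf = inner.add_child(
            Node(lab, rng.uniform(0.1, 2.0) if with_lengths else None)
        )
        leaves.append(new_leaf)
    return Tree(root)


def all_rooted_trees(labels) -> list[Tree]:
    """Every rooted binary leaf-labeled tree on the given labels."""

    def build(labs) -> list:
        if len(labs) == 1:
            return [("leaf", labs[0])]
        out = []
        first, rest = labs[0], labs[1:]
        # left subtree is every subset containing the first label
        for r in range(len(rest) + 1):
            for right in itertools.combinations(rest, r):
                left = [first] + [x for x in rest if x not in right]
                if not right:
                    continue
                for lt in build(left):
                    for rt in build(list(right)):
                        out.append(("node", lt, rt))
        return out

    def to_tree(shape) -> Node:
        if shape[0] == "leaf":
            return Node(shape[1])
        n = Node()
        n.add_child(to_tree(shape[1]))
        n.add_child(to_tree(shape[2]))
        return n

    return [Tree(to_tree(s)) for s in build(list(labels))]


def tree_canonical(tree: Tree) -> tuple:
    """Order-independent encoding of topology, labels, and lengths."""

    def rec(n: Node):
        if n.is_leaf:
            return ("L", n.name, None if n.length is None else round(n.length, 9))
        kids = tuple(sorted(rec(c) for c in n.children))
        return ("N", kids, None if n.length is None else round(n.length, 9))

    return rec(tree.root)


# ---------------------------------------------------------------------------
# LCA by ancestor-set intersection


def lca_oracle(tree: Tree, names) -> Node:
    def ancestors(n: Node):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    paths = [ancestors(tree.leaf(x)) for x in names]
    common = set(id(a) for a in paths[0])
    for p in paths[1:]:
        common &= {id(a) for a in p}
    for a in paths[0]:  # deepest first
        if id(a) in common:
            return a
    raise AssertionError("no common ancestor")


# ---------------------------------------------------------------------------
# Dollo: exhaustive minimization over single-gain loss placements


def dollo_oracle(present: set, tree: Tree):
    """Try every gain node whose subtree covers the carriers; the losses
    forced by a gain are the maximal empty subtrees below it.  Returns
    (best gain node, loss branch set, loss count) minimizing losses."""
    carriers = {}
    for n in tree.root.postorder():
        if n.is_leaf:
            carriers[id(n)] = 1 if n.name in present else 0
        else:
            carriers[id(n)] = sum(carriers[id(c)] for c in n.children)
    total = carriers[id(tree.root)]

    def forced_losses(v: Node):
        losses = set()
        stack = [v]
        while stack:
            n = stack.pop()
            for c in n.children:
                if carriers[id(c)] == 0:
                    losses.add(c.canonical_name)
                else:
                    stack.append(c)
        return losses

    best = None
    for v in tree.preorder():
        if carriers[id(v)] == total:  # subtree covers every carrier
            losses = forced_losses(v)
            cand = (len(losses), v, losses)
            if best is None or cand[0] < best[0]:
                best = cand
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# reconciliation: exhaustive minimization over mappings


def reconcile_oracle(gt: Tree, st: Tree, species_map: dict):
    """Minimum duplication+loss over all valid gene->species mappings.

    A mapping sends each internal gene node g to any ancestor-or-equal
    of the LCA of its children's images.  g is a speciation iff its
    children's images lie in distinct child subtrees of its image;
    otherwise a duplication.  Losses follow the standard path-length
    accounting.  Returns (min cost, min dups among min-cost mappings).
    """
    depth = {}
    parent = {}
    for n in st.preorder():
        parent[id(n)] = n.parent
        depth[id(n)] = 0 if n.parent is None else depth[id(n.parent)] + 1

    def lca(a, b):
        while a is not b:
            if depth[id(a)] < depth[id(b)]:
                b = b.parent
            elif depth[id(a)] > depth[id(b)]:
                a = a.parent
            else:
                a, b = a.parent, b.parent
        return a

    def ancestors_incl(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    def dist(top, bottom):
        d = 0
        n = bottom
        while n is not top:
            n = n.parent
            d += 1
        return d

    def child_subtree_of(s, x):
        """Which child of s contains x (x strictly below s)."""
        n = x
        while n.parent is not s:
            n = n.parent
        return n

    gnodes = list(gt.postorder())
    internal = [g for g in gnodes if not g.is_leaf]
    leaf_image = {id(g): st.leaf(species_map[g.name]) for g in gnodes if g.is_leaf}

    best = [None]

    def rec(i, images, cost, dups):
        if best[0] is not None and (cost, dups) >= best[0]:
            return
        if i == len(internal):
            cand = (cost, dups)
            if best[0] is None or cand < best[0]:
                best[0] = cand
            return
        g = internal[i]
        img = [images[id(c)] for c in g.children]
        low = lca(img[0], img[1])
        for s in ancestors_incl(low):
            c1, c2 = img
            if s is low and c1 is not s and c2 is not s:
                # speciation possible only if children split at s
                spec = child_subtree_of(s, c1) is not child_subtree_of(s, c2)
            else:
                spec = False
            if spec:
                add_cost = (dist(s, c1) - 1) + (dist(s, c2) - 1)
                add_dup = 0
            else:
                add_cost = 1 + dist(s, c1) + dist(s, c2)
                add_dup = 1
            images[id(g)] = s
            rec(i + 1, images, cost + add_cost, dups + add_dup)
        del images[id(g)]

    rec(0, dict(leaf_image), 0, 0)
    return best[0]


def random_gene_tree(n: int, species, rng: random.Random) -> tuple[Tree, dict]:
    labels = [f"g{i}" for i in range(n)]
    t = random_rooted_tree(labels, rng, with_lengths=False)
    smap = {l: rng.choice(list(species)) for l in labels}
    return t, smap


# ---------------------------------------------------------------------------
# additive distance matrices


def random_additive_matrix(n: int, rng: random.Random):
    """(DataFrame distance matrix, generating Tree) for an additive metric."""
    import pandas as pd

    labels = [f"t{i}" for i in range(n)]
    tree = random_rooted_tree(labels, rng, with_lengths=True)
    # path lengths between leaves
    def depth_map():
        d = {}

        def rec(node, acc):
            d[id(node)] = acc
            for c in node.children:
                rec(c, acc + c.length)

        rec(tree.root, 0.0)
        return d

    d = depth_map()
    anc = {}
    for name in labels:
        chain = []
        x = tree.leaf(name)
        while x is not None:
            chain.append(x)
            x = x.parent
        anc[name] = chain
    import numpy as np

    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        aset = {id(x) for x in anc[a]}
        for j in range(i + 1, n):
            b = labels[j]
            x = tree.leaf(b)
            while id(x) not in aset:
                x = x.parent
            m[i, j] = m[j, i] = (
                d[id(tree.leaf(a))] + d[id(tree.leaf(b))] - 2 * d[id(x)]
            )
    return pd.DataFrame(m, index=labels, columns=labels), tree


def unrooted_splits(adj_tree) -> set:
    """Nontrivial splits of an UnrootedTree as frozensets of one side."""
    out = set()
    for u, v, _ in adj_tree.edges():
        side = frozenset(adj_tree.leaf_side(u, v))
        if 1 < len(side) < len(adj_tree.leaves) - 1:
            all_leaves = frozenset(adj_tree.labels.values())
            out.add(min(side, all_leaves - side, key=sorted))
    return out


def rooted_tree_splits(tree: Tree) -> set:
    """Nontrivial unrooted splits implied by a rooted tree."""
    all_leaves = frozenset(tree.leaf_names)
    out = set()
    for n in tree.preorder():
        if n is tree.root or n.is_leaf:
            continue
        side = frozenset(x.name for x in n.iter_leaves())
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(min(side, all_leaves - side, key=sorted))
    return out
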