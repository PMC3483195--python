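"""Gene-tree/species-tree reconciliation by LCA mapping.

Each gene-tree node is mapped to the LCA (in the species tree) of the
species of its descendant genes.  A node whose mapping equals a child's
mapping is a duplication; every other internal node is a speciation.
Losses are read off the species-tree path between a node's mapping and
each child's mapping: each species node skipped on the way down implies
a gene lineage lost on the sibling branch.  This mapping attains the
minimum duplication + loss cost among all reconciliations of a rooted
gene tree, and unrooted gene trees are rooted by evaluating every edge
and keeping the cheapest rooting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .trees import Node, Tree, UnrootedTree

__all__ = ["ReconciliationResult", "reconcile", "root_by_min_cost", "aggregate"]


@dataclass
class ReconciliationResult:
    duplications: dict[str, int]  # species branch canonical name -> count
    losses: dict[str, int]
    rooting_edge: tuple | None = None

    @property
    def n_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())

    @property
    def cost(self) -> int:
        return self.n_duplications + self.n_losses


def _species_index(st: Tree):
    depth = {}
    parent = {}
    for n in st.preorder():
        parent[id(n)] = n.parent
        depth[id(n)] = 0 if n.parent is None else depth[id(n.parent)] + 1
    return depth, parent


def _st_lca(a: Node, b: Node, depth) -> Node:
    while a is not b:
        if depth[id(a)] < depth[id(b)]:
            b = b.parent
        elif depth[id(a)] > depth[id(b)]:
            a = a.parent
        else:
            a, b = a.parent, b.parent
    return a


def reconcile(
    gt: Tree, st: Tree, species_map: dict[str, str]
) -> ReconciliationResult:
    """LCA-mapping reconciliation of a rooted binary gene tree.

    ``species_map`` sends gene-tree leaf labels to species-tree leaf
    labels.  Duplications are charged to the branch above the mapped
    node; each loss is charged to the species branch it skips (the
    sibling branch of each species node passed without speciating).
    """
    depth, _ = _species_index(st)
    dup: dict[str, int] = {}
    loss: dict[str, int] = {}
    mapping: dict[int, Node] = {}

    def branch_name(sn: Node) -> str:
        # the branch above sn; the root has a virtual branch
        return sn.canonical_name if sn.parent is not None else "@root"

    def charge_losses(top: Node, bottom: Node, include_top: bool) -> None:
        """Losses on sibling branches along the path bottom -> top."""
        n = bottom
        while n is not top:
            p = n.parent
            if p is not top or include_top:
                for sib in p.children:
                    if sib is not n:
                        loss[sib.canonical_name] = loss.get(sib.canonical_name, 0) + 1
            n = p

    for g in gt.postorder():
        if g.is_leaf:
            try:
                sp = species_map[g.name]
            except KeyError:
                raise KeyError(f"gene {g.name!r} has no species mapping") from None
            mapping[id(g)] = st.leaf(sp)
        else:
            if len(g.children) != 2:
                raise ValueError("gene tree must be binary")
            a, b = (mapping[id(c)] for c in g.children)
            m = _st_lca(a, b, depth)
            mapping[id(g)] = m
            is_dup = any(mapping[id(c)] is m for c in g.children)
            if is_dup:
                bn = branch_name(m)
                dup[bn] = dup.get(bn, 0) + 1
            for c in g.children:
                mc = mapping[id(c)]
                if mc is not m:
                    # speciation: skip siblings strictly between; duplication:
                    # also the speciation at m itself
                    charge_losses(m, mc, include_top=is_dup)
                # if mc is m and is_dup: no loss on that side

    return ReconciliationResult(dup, loss)


def root_by_min_cost(
    ut: UnrootedTree, st: Tree, species_map: dict[str, str]
) -> tuple[Tree, ReconciliationResult]:
    """Root an unrooted gene tree on the edge minimizing duplication+loss.

    Ties are broken by fewer duplications, then by the smallest canonical
    edge label (the sorted leaf set of the smaller side).
    """
    best = None
    for (u, v), rooted in ut.rootings():
        res = reconcile(rooted, st, species_map)
        side_u = ut.leaf_side(u, v)
        side_v = ut.leaf_side(v, u)
        label = min(",".join(side_u), ",".join(side_v))
        cand = (res.cost, res.n_duplications, label, (u, v), rooted, res)
        if best is None or cand[:3] < best[:3]:
            best = cand
    _, _, _, edge, rooted, res = best
    res.rooting_edge = edge
    return rooted, res


def aggregate(
    results: list[tuple[str, int, ReconciliationResult]],
    st: Tree,
    size_cap: int = 1000,
) -> tuple[pd.DataFrame, list[str]]:
    """Sum per-branch duplication/loss counts over many reconciliations.

    ``results`` holds (identifier, gene-tree leaf count, result) triples;
    trees with more than ``size_cap`` leaves are excluded and reported,
    mirroring the exclusion of oversized families from tree building.
    Returns (per-branch totals, excluded identifiers).
    """
    branches = ["@root"] + [b.canonical_name for b in st.branches()]
    totals = pd.DataFrame(0, index=branches, columns=["duplications", "losses"])
    excluded = []
    for ident, nleaves, res in results:
        if nleaves > size_cap:
            excluded.append(ident)
            continue
        for b, c in res.duplications.items():
            totals.loc[b, "duplications"] += c
        for b, c in res.losses.items():
            totals.loc[b, "losses"] += c
    return totals, excluded
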