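"""Protein families by Markov clustering (MCL) of a similarity graph.

Families are built the way large-scale orthology pipelines build them:
an all-against-all similarity search is condensed into a weighted
undirected graph, the graph is clustered with MCL at inflation 2.0, and
every multi-member cluster becomes a protein family.

The weight convention converts E-values to ``min(-log10(E), 200)`` and
symmetrizes by averaging the two search directions; E = 0 maps to the
cap.  The convention is configurable — any pre-weighted edge list in ABC
format is accepted as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimilarityGraph",
    "Family",
    "weights_from_search",
    "read_abc",
    "mcl",
    "families_from_clusters",
    "read_search_tsv",
]

EVALUE_CAP = 200.0  # -log10 weight cap; E = 0 maps here


@dataclass
class SimilarityGraph:
    """Undirected weighted graph over protein ids (no stored self-edges)."""

    nodes: list[str] = field(default_factory=list)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def add_node(self, n: str) -> None:
        if n not in self._index:
            self._index[n] = len(self.nodes)
            self.nodes.append(n)

    def __post_init__(self):
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def add_edge(self, u: str, v: str, w: float) -> None:
        if u == v:
            return
        if not np.isfinite(w) or w < 0:
            raise ValueError(f"invalid edge weight {w!r} for ({u}, {v})")
        self.add_node(u)
        self.add_node(v)
        key = (u, v) if u < v else (v, u)
        self.edges[key] = max(w, self.edges.get(key, 0.0))

    def to_sparse(self) -> sp.csr_matrix:
        n = len(self.nodes)
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows, cols, vals = [], [], []
        for (u, v), w in self.edges.items():
            i, j = self._index[u], self._index[v]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def weights_from_search(hits: pd.DataFrame) -> SimilarityGraph:
    """Build a similarity graph from tabular search hits.

    ``hits`` needs columns query, subject, evalue.  The weight of an edge
    is the mean over both directions of ``min(-log10(E), 200)`` with E = 0
    mapped to 200; self-hits are dropped.
    """
    if (hits["evalue"] < 0).any():
        raise ValueError("negative E-value in search hits")
    g = SimilarityGraph()
    acc: dict[tuple[str, str], list[float]] = {}
    for q, s, e in zip(hits["query"], hits["subject"], hits["evalue"]):
        if q == s:
            continue
        w = EVALUE_CAP if e == 0 else min(-np.log10(e), EVALUE_CAP)
        key = (q, s) if q < s else (s, q)
        acc.setdefault(key, []).append(float(w))
        g.add_node(q)
        g.add_node(s)
    for (u, v), ws in acc.items():
        g.add_edge(u, v, float(np.mean(ws)))
    return g


def read_search_tsv(path) -> pd.DataFrame:
    """Read 12-column tabular search output (query, subject, ..., evalue, bits)."""
    cols = [
        "query", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    return pd.read_csv(path, sep="\t", names=cols, comment="#")


def read_abc(path) -> SimilarityGraph:
    """Read a tab-separated ABC edge list (node1, node2, weight)."""
    g = SimilarityGraph()
    df = pd.read_csv(path, sep="\t", names=["u", "v", "w"], comment="#")
    for u, v, w in zip(df["u"], df["v"], df["w"]):
        g.add_edge(str(u), str(v), float(w))
    return g


def _normalize_columns(m: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return (m @ sp.diags(1.0 / sums)).tocsr()


def mcl(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> list[set[str]]:
    """Markov clustering of a similarity graph.

    Classic MCL: self-loops (weight = max incident weight, 1 for isolated
    nodes) are added, columns are normalized, and expansion (matrix
    squaring) alternates with inflation (entrywise power + renormalize)
    and pruning of entries below ``prune_threshold`` until the matrix is
    stable.  Clusters are the connected components of the converged
    attractor structure; a node attracted to several attractors is placed
    with its largest converged weight, ties going to the lexicographically
    smallest cluster.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must exceed 1, got {inflation}")
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    a = graph.to_sparse()
    maxw = np.asarray(a.max(axis=0).todense()).ravel() if a.nnz else np.zeros(n)
    loops = np.where(maxw > 0, maxw, 1.0)
    m = _normalize_columns((a + sp.diags(loops)).tocsr())
    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m  # expansion
        m = m.power(inflation)  # inflation
        m = _normalize_columns(m)
        m.data[m.data < prune_threshold] = 0.0
        m.eliminate_zeros()
        m = _normalize_columns(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; returning current clustering")

    # attractors are rows with nonzero diagonal; read clusters from the
    # attractor structure of the converged matrix
    csr = m.tocsr()
    diag = csr.diagonal()
    attractors = np.where(diag > tol)[0]
    if len(attractors) == 0:  # degenerate; treat every row as an attractor
        attractors = np.arange(n)
    attractor_set = set(int(a) for a in attractors)
    # columns record which attractors pull each node; attractors sharing a
    # column belong to one overlapping attractor system
    col_sets: dict[int, list[int]] = {}
    coo = csr.tocoo()
    for r, c, v in zip(coo.row, coo.col, coo.data):
        if v > tol and int(r) in attractor_set:
            col_sets.setdefault(int(c), []).append(int(r))
    # union-find over attractors
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for rs in col_sets.values():
        for r in rs[1:]:
            union(rs[0], r)

    # smallest member label per attractor system, for deterministic ids
    root_label: dict[int, str] = {}
    for x in parent:
        rt = find(x)
        lbl = nodes[x]
        if rt not in root_label or lbl < root_label[rt]:
            root_label[rt] = lbl

    # assign every node to the attractor system holding its largest weight
    weight_of = {}
    for r, c, v in zip(coo.row, coo.col, coo.data):
        weight_of[(int(r), int(c))] = float(v)
    assign: dict[int, tuple[float, str, int]] = {}
    for c, rs in col_sets.items():
        for r in rs:
            root = find(r)
            cand = (weight_of[(r, c)], root_label[root], root)
            cur = assign.get(c)
            if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
                assign[c] = cand
    clusters: dict[int, set[str]] = {}
    for c in range(n):
        if c in assign:
            clusters.setdefault(assign[c][2], set()).add(nodes[c])
        else:  # node lost all mass (isolated after pruning): singleton
            clusters.setdefault(-c - 1, set()).add(nodes[c])
    return sorted(clusters.values(), key=lambda s: (-len(s), min(s)))


@dataclass(frozen=True)
class Family:
    """A protein family: an MCL cluster with at least two members."""

    family_id: str
    members: frozenset[str]

    @property
    def species(self) -> frozenset[str]:
        return frozenset(m.split("_", 1)[0] for m in self.members)


def families_from_clusters(clusters: list[set[str]]) -> list[Family]:
    """Multi-member clusters become families, numbered by descending size
    then lexicographically smallest member."""
    multi = [c for c in clusters if len(c) >= 2]
    multi.sort(key=lambda c: (-len(c), min(c)))
    return [
        Family(f"F{i + 1}", frozenset(c)) for i, c in enumerate(multi)
    ]


def families_to_frame(families: list[Family]) -> pd.DataFrame:
    rows = [
        (f.family_id, m, m.split("_", 1)[0])
        for f in families
        for m in sorted(f.members)
    ]
    return pd.DataFrame(rows, columns=["family_id", "protein_id", "species"])
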