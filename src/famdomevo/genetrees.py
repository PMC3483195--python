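"""Protein distance matrices and neighbor-joining gene trees.

Downstream reconciliation uses gene-tree *topology* only, so a fast
distance + NJ stage stands in for likelihood tree building.  Two
distance models are provided: uncorrected p-distance and the Kimura
protein correction d = -ln(1 - p - p^2/5); saturated pairs (p >= 0.85)
receive a finite ceiling so NJ stays defined.  Precomputed distance
matrices in PHYLIP square format are accepted as an injection point for
external distance estimators.

NJ is the classic Saitou–Nei agglomeration with the Q criterion; joins
are tie-broken on the lexicographically smallest taxon-pair label so the
output is invariant to input order.  Negative branch length estimates
are clamped to zero with the deficit moved to the sibling branch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trees import UnrootedTree

__all__ = [
    "read_fasta_alignment",
    "pairwise_distance",
    "read_phylip_square",
    "write_phylip_square",
    "neighbor_joining",
]

GAP_CHARS = set("-.")
KIMURA_SATURATION = 0.85


def read_fasta_alignment(path) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered id -> sequence mapping."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    return seqs


def pairwise_distance(
    aln: dict[str, str], model: str = "p", saturation_ceiling: float = 10.0
) -> pd.DataFrame:
    """Pairwise distances under the p or Kimura model.

    Gap columns are deleted pairwise; a pair with no comparable site is
    an error.  Under ``"kimura"``, p >= 0.85 maps to
    ``saturation_ceiling``.
    """
    if model not in ("p", "kimura"):
        raise ValueError(f"unknown distance model {model!r}")
    names = list(aln)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(aln[n]) for n in names])
    valid = ~np.isin(arr, list(GAP_CHARS))
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            sites = int(both.sum())
            if sites == 0:
                raise ValueError(
                    f"no comparable sites between {names[i]!r} and {names[j]!r}"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / sites
            if model == "p":
                dist = p
            else:
                if p >= KIMURA_SATURATION:
                    dist = saturation_ceiling
                else:
                    dist = -np.log(1.0 - p - 0.2 * p * p)
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=names, columns=names)


def read_phylip_square(path) -> pd.DataFrame:
    """Read a PHYLIP square (non-interleaved) distance matrix."""
    with open(path) as fh:
        tokens = fh.read().split()
    n = int(tokens[0])
    names, rows = [], []
    pos = 1
    for _ in range(n):
        names.append(tokens[pos])
        rows.append([float(x) for x in tokens[pos + 1 : pos + 1 + n]])
        pos += 1 + n
    return pd.DataFrame(rows, index=names, columns=names)


def write_phylip_square(dm: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for name in dm.index:
            vals = " ".join(f"{v:.10f}" for v in dm.loc[name])
            fh.write(f"{name} {vals}\n")


def neighbor_joining(dm: pd.DataFrame) -> UnrootedTree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix."""
    names = list(dm.index)
    d = dm.to_numpy(dtype=float).copy()
    if d.shape[0] != d.shape[1] or np.nanmax(np.abs(d - d.T)) > 1e-9:
        raise ValueError("distance matrix is not symmetric")
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tree = UnrootedTree()
    node_of = {i: tree.new_node(names[i]) for i in range(n)}
    # labels used for deterministic tie-breaking: smallest leaf under node
    tag = {i: names[i] for i in range(n)}
    active = list(range(n))
    D = {(i, j): d[i, j] for i in range(n) for j in range(n)}

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[(i, j)] - r[i] - r[j]
                pair_tag = tuple(sorted((tag[i], tag[j])))
                cand = (q, pair_tag, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = D[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = max(active) + 1
        u = tree.new_node()
        tree.add_edge(u, node_of[i], li)
        tree.add_edge(u, node_of[j], lj)
        node_of[new] = u
        tag[new] = min(tag[i], tag[j])
        for k in active:
            if k in (i, j):
                continue
            D[(new, k)] = D[(k, new)] = 0.5 * (D[(i, k)] + D[(j, k)] - dij)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j = active
    tree.add_edge(node_of[i], node_of[j], max(D[(i, j)], 0.0))
    return tree
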