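"""Dollo-parsimony birth/death reconstruction of presence/absence characters.

Each protein family (or domain) is a binary character over the taxa: 1
where the species has at least one member, 0 otherwise.  Under Dollo
parsimony a character is gained exactly once — on the branch above the
LCA of the taxa that carry it — and may only be lost afterwards; the
minimal loss set is the set of branches into the maximal subtrees of the
birth clade that contain no carrier.  Per-branch sums of these events
over all characters give the lineage birth/death table.

Ancient-node overestimation inherent to Dollo reconstruction is left
uncorrected, mirroring common practice for gene-content characters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import CLADES, Node, Tree

__all__ = [
    "presence_matrix",
    "dollo_reconstruct",
    "count_events",
    "classify_family",
    "unique_losses",
    "new_family_domain_overlap",
]

ROOT_BRANCH = "@root"  # virtual branch above the root (no length)


def presence_matrix(groups: dict[str, set[str]], taxa: list[str]) -> pd.DataFrame:
    """Binary characters × taxa matrix from per-character species sets.

    ``groups`` maps character id -> set of species carrying it.  A
    character present in no taxon, or naming an unknown taxon, is an
    error.
    """
    taxa = list(taxa)
    taxon_set = set(taxa)
    rows = {}
    for cid, species in groups.items():
        unknown = set(species) - taxon_set
        if unknown:
            raise ValueError(f"character {cid!r} names unknown taxa {sorted(unknown)}")
        if not species:
            raise ValueError(f"character {cid!r} is present in no taxon")
        rows[cid] = [1 if t in species else 0 for t in taxa]
    m = pd.DataFrame.from_dict(rows, orient="index", columns=taxa, dtype=np.int8)
    return m.sort_index()


def dollo_reconstruct(present: set[str], tree: Tree) -> tuple[str, set[str]]:
    """Single-gain, minimal-loss reconstruction of one character.

    Returns ``(birth_branch, loss_branches)`` where branches are named by
    the canonical name of their head node; a character present at the
    root's full leaf set is born on the virtual root branch ``@root``.
    Losses are the branches into maximal empty subtrees of the birth
    clade; this loss count is minimal among single-gain scenarios.
    """
    if not present:
        raise ValueError("character present in no taxon")
    birth_node = tree.lca(present)
    # count carriers per subtree
    carriers: dict[int, int] = {}
    for n in birth_node.postorder():
        if n.is_leaf:
            carriers[id(n)] = 1 if n.name in present else 0
        else:
            carriers[id(n)] = sum(carriers[id(c)] for c in n.children)
    losses: set[str] = set()

    def walk(n: Node) -> None:
        for c in n.children:
            if carriers[id(c)] == 0:
                losses.add(c.canonical_name)
            else:
                walk(c)

    walk(birth_node)
    birth = ROOT_BRANCH if birth_node is tree.root else birth_node.canonical_name
    return birth, losses


def count_events(matrix: pd.DataFrame, tree: Tree) -> pd.DataFrame:
    """Per-branch birth and death counts summed over all characters.

    Returns a frame indexed by branch canonical name (plus the virtual
    root branch) with columns ``birth`` and ``death``.
    """
    branches = [ROOT_BRANCH] + [b.canonical_name for b in tree.branches()]
    birth = {b: 0 for b in branches}
    death = {b: 0 for b in branches}
    taxa = list(matrix.columns)
    values = matrix.to_numpy()
    for i in range(values.shape[0]):
        present = {taxa[j] for j in np.nonzero(values[i])[0]}
        b, losses = dollo_reconstruct(present, tree)
        birth[b] += 1
        for l in losses:
            death[l] += 1
    out = pd.DataFrame({"birth": birth, "death": death}).loc[branches]
    out.index.name = "branch"
    return out


def classify_family(present: set[str], clades: dict[str, frozenset] = CLADES) -> str:
    """Taxonomic category of a character's species distribution.

    ``universal`` (all 11 taxa), ``clade_specific_single_species``,
    ``clade_specific_shared`` (confined to one metazoan clade), or
    ``other``.
    """
    all_taxa = set().union(*clades.values()) | {"Sce", "Mbr"}
    if present == all_taxa:
        return "universal"
    for members in clades.values():
        if present <= members:
            if len(present) == 1:
                return "clade_specific_single_species"
            return "clade_specific_shared"
    return "other"


def unique_losses(matrix: pd.DataFrame) -> pd.Series:
    """Per-species counts of characters absent from exactly that species.

    A unique loss of species *s* is a character present in every other
    taxon but absent from *s*.
    """
    values = matrix.to_numpy()
    zeros = (values == 0).sum(axis=1)
    single = values[zeros == 1]
    counts = (single == 0).sum(axis=0)
    return pd.Series(counts, index=matrix.columns, name="unique_losses")


@dataclass(frozen=True)
class BranchDomainSet:
    branch: str
    domains: frozenset[str]
    universal_overlap: int


def new_family_domain_overlap(
    birth_assignments: dict[str, str],
    family_domains: dict[str, set[str]],
    universal_families: set[str],
    branches: list[str],
) -> dict:
    """Domain content of families born on selected branches and overlaps.

    ``birth_assignments`` maps family id -> birth branch;
    ``family_domains`` maps family id -> domain accessions found in it.
    Returns, per queried branch, the domain set, its size, its overlap
    with the universal families' domains, and pairwise overlaps between
    the queried branches.
    """
    universal_domains: set[str] = set()
    for f in universal_families:
        universal_domains |= family_domains.get(f, set())
    per_branch: dict[str, set[str]] = {b: set() for b in branches}
    for fam, b in birth_assignments.items():
        if b in per_branch:
            per_branch[b] |= family_domains.get(fam, set())
    result = {
        "branch_domains": {b: frozenset(d) for b, d in per_branch.items()},
        "sizes": {b: len(d) for b, d in per_branch.items()},
        "universal_overlap": {
            b: len(d & universal_domains) for b, d in per_branch.items()
        },
        "pairwise_overlap": {
            (a, b): len(per_branch[a] & per_branch[b])
            for i, a in enumerate(branches)
            for b in branches[i + 1 :]
        },
    }
    return result
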