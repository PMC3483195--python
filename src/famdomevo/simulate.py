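"""Forward simulation of family/domain evolution with recorded ground truth.

The generator walks the species tree from the root, carrying a genome of
protein families.  Along each branch, event counts are drawn from
Poisson distributions with exposure proportional to branch length and to
the current number of families (family birth/death, standalone domain
gain) or members (member duplication/deletion).  New families are
founded either on one brand-new domain (de novo) or on domains sampled
from two distinct existing families (shuffling).  Families obey a
single-origin constraint — a dead family never reappears — so every
simulated history is Dollo-consistent; an optional violating mode
re-activates dead families to demonstrate parsimony undercounting.

Sequences are never simulated: pairwise distances are taken directly
from path lengths on the true gene trees (plus optional Gaussian noise),
which keeps the simulator exactly invertible at zero noise, because the
pipeline only uses gene-tree topology downstream.

With ``constrain_losses`` (default), family deaths are additionally kept
off sister branches and off the child branches of a family's birth node;
in that regime Dollo parsimony recovers every birth and death exactly,
which is the acceptance surface of the end-to-end tests.

Every event is logged; :class:`GroundTruth` tallies always equal the
event log.
"""

from __future__ import annotations

import json
import zlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trees import Node, Tree, species_tree, write_newick

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SyntheticDataset",
    "simulate",
    "emit",
    "plant_enrichment",
    "MINI_OBO",
]

ROOT_BRANCH = "@root"


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the synthetic benchmark.

    Rates are per unit branch length; family-level rates use the current
    family count as exposure, member-level rates the current member
    count.  Defaults are the documented desk-scale, moderate-noise
    conditions; ``zero_noise()`` switches the observation noise off.
    """

    n_root_families: int = 150
    mean_members: float = 2.0  # geometric mean member count of root families
    fam_birth_rate: float = 0.15
    denovo_fraction: float = 0.3  # family births founded on a brand-new domain
    fam_death_rate: float = 0.05
    dup_rate: float = 0.15
    del_rate: float = 0.10
    dom_birth_rate: float = 0.02  # standalone domain gains into existing families
    distance_noise_sd: float = 0.02
    false_edge_prob: float = 0.005  # expected false edges per protein
    drop_edge_prob: float = 0.01
    intra_weight: float = 100.0
    false_weight: float = 10.0
    constrain_losses: bool = True
    allow_rebirth: bool = False

    def zero_noise(self) -> "SimulationParams":
        return replace(
            self, distance_noise_sd=0.0, false_edge_prob=0.0, drop_edge_prob=0.0
        )

    def duplication_only(self) -> "SimulationParams":
        """No deaths or deletions: the regime where reconciliation localizes
        every duplication exactly."""
        return replace(self.zero_noise(), fam_death_rate=0.0, del_rate=0.0)


class _GNode:
    __slots__ = ("name", "length", "children", "parent", "born_at", "dead")

    def __init__(self, parent=None, born_at=0.0):
        self.name = None
        self.length = 0.0
        self.children = []
        self.parent = parent
        self.born_at = born_at
        self.dead = False
        if parent is not None:
            parent.children.append(self)


@dataclass
class _Fam:
    fid: str
    birth_branch: str
    birth_head: int  # id() of the species node heading the birth branch
    root: _GNode
    arch0: tuple  # founding architecture
    death_branches: set = field(default_factory=set)


@dataclass
class GroundTruth:
    """Per-branch true event counts and per-family histories."""

    events: pd.DataFrame  # branch × (fam_birth, fam_death, dom_birth, dom_death, member_dup, member_del)
    birth_branch: dict
    death_branches: dict
    gene_trees: dict  # fid -> newick of the pruned true gene tree
    members: dict  # fid -> list of protein ids
    architectures: dict  # fid -> {species: tuple of domains} local architectures
    universal_families: list


@dataclass
class SyntheticDataset:
    species_tree: Tree
    proteins: pd.DataFrame  # protein_id, species (truth column: family)
    edges: pd.DataFrame  # u, v, w
    domain_hits: pd.DataFrame  # protein, domain, start, end, score, evalue
    distance_matrices: dict  # fid -> DataFrame
    annotations: pd.DataFrame  # protein_id, term_id
    obo_text: str
    truth: GroundTruth


def _branch_rng(seed: int, branch: str, salt: str = "") -> np.random.Generator:
    h = zlib.crc32((branch + "|" + salt).encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, h])


# A fixed miniature biological-process-style ontology for planting
# enrichments: one root, two mid-level terms, four leaves.
MINI_OBO = """format-version: 1.2
ontology: mini

[Term]
id: T:0001
name: biological process

[Term]
id: T:0100
name: signaling
is_a: T:0001

[Term]
id: T:0200
name: metabolism
is_a: T:0001

[Term]
id: T:0101
name: receptor signaling
is_a: T:0100

[Term]
id: T:0102
name: signal transduction
is_a: T:0100

[Term]
id: T:0201
name: carbohydrate metabolism
is_a: T:0200

[Term]
id: T:0202
name: lipid metabolism
is_a: T:0200
"""

OBO_LEAVES = ["T:0101", "T:0102", "T:0201", "T:0202"]


def simulate(
    params: SimulationParams, seed: int, tree: Tree | None = None
) -> SyntheticDataset:
    """Run the forward simulation and assemble every pipeline input.

    Deterministic for a fixed seed: per-branch random streams are derived
    from the master seed by stable hashing of branch names, so the same
    seed yields byte-identical emitted files.
    """
    st = tree if tree is not None else species_tree()
    branches = [ROOT_BRANCH] + [b.canonical_name for b in st.branches()]
    counts = {
        b: dict.fromkeys(
            ["fam_birth", "fam_death", "dom_birth", "dom_death", "member_dup", "member_del"],
            0,
        )
        for b in branches
    }

    fams: dict[str, _Fam] = {}
    next_fid = [0]
    next_dom = [0]

    def new_fid() -> str:
        next_fid[0] += 1
        return f"f{next_fid[0]}"

    def new_dom(branch: str) -> str:
        # domain birth/death counts are derived from per-node genome
        # differences after the traversal
        next_dom[0] += 1
        return f"d{next_dom[0]}"

    # --- root genome ------------------------------------------------------
    rng0 = _branch_rng(seed, ROOT_BRANCH)
    root_state: dict[str, dict] = {}
    for _ in range(params.n_root_families):
        fid = new_fid()
        ndom = 1 + int(rng0.poisson(0.5))
        arch = tuple(new_dom(ROOT_BRANCH) for _ in range(ndom))
        m = max(2, int(rng0.geometric(1.0 / params.mean_members)))
        counts[ROOT_BRANCH]["fam_birth"] += 1
        root = _GNode()
        tips = [root]
        # pre-root duplication burst with small waiting times so internal
        # edges of the founding tree are positive and distinct
        while len(tips) < m:
            dt = 0.02 * float(rng0.exponential()) + 1e-4
            for t in tips:
                t.length += dt
            t = tips[int(rng0.integers(len(tips)))]
            c1, c2 = _GNode(t), _GNode(t)
            tips.remove(t)
            tips += [c1, c2]
            counts[ROOT_BRANCH]["member_dup"] += 1
        dt = 0.02 * float(rng0.exponential()) + 1e-4
        for t in tips:
            t.length += dt
        fams[fid] = _Fam(fid, ROOT_BRANCH, id(st.root), root, arch)
        root_state[fid] = {"tips": tips, "arch": list(arch)}

    # genome (family set + local architectures) recorded per species node
    genome_at: dict[int, dict[str, tuple]] = {
        id(st.root): {f: tuple(s["arch"]) for f, s in root_state.items()}
    }
    proteins: list[tuple[str, str, str]] = []  # protein, species, family
    leaf_arch: dict[str, dict[str, tuple]] = {}  # fid -> species -> arch

    deaths_on: dict[str, set] = {b: set() for b in branches}

    def process_branch(parent_node: Node, child: Node, state: dict) -> dict:
        """Evolve ``state`` along the branch into ``child``; returns the
        state at the child node."""
        bn = child.canonical_name
        l = child.length if child.length is not None else 0.0
        rng = _branch_rng(seed, bn)
        # copy state: one new gene-tree node per surviving lineage
        st_here: dict[str, dict] = {}
        for fid, s in state.items():
            tips = [_GNode(t) for t in s["tips"]]
            st_here[fid] = {"tips": tips, "arch": list(s["arch"])}

        alive = sorted(st_here)
        n_alive = len(alive)

        # --- family deaths -----------------------------------------------
        n_death = int(rng.poisson(params.fam_death_rate * l * n_alive))
        eligible = list(alive)
        if params.constrain_losses:
            sister_dead = set()
            for sib in parent_node.children:
                if sib is not child:
                    sister_dead |= deaths_on[sib.canonical_name]
            eligible = [
                f
                for f in eligible
                if f not in sister_dead and id(parent_node) != fams[f].birth_head
            ]
        rng.shuffle(eligible)
        for f in eligible[: min(n_death, len(eligible))]:
            u = float(rng.uniform(0, l)) if l > 0 else 0.0
            for t in st_here[f]["tips"]:
                t.length += max(u - t.born_at, 0.0)
                t.dead = True
            del st_here[f]
            fams[f].death_branches.add(bn)
            deaths_on[bn].add(f)
            counts[bn]["fam_death"] += 1

        # --- family births -----------------------------------------------
        n_birth = int(rng.poisson(params.fam_birth_rate * l * n_alive))
        for _ in range(n_birth):
            reborn = None
            if params.allow_rebirth:
                dead = sorted(
                    f for f in fams if f not in st_here and fams[f].death_branches
                )
                if dead and rng.random() < 0.2:
                    reborn = dead[int(rng.integers(len(dead)))]
            u = float(rng.uniform(0, l)) if l > 0 else 0.0
            if reborn is not None:
                fid = reborn
                arch = list(fams[fid].arch0)
            else:
                fid = new_fid()
                donors = sorted(st_here)
                if rng.random() < params.denovo_fraction or len(donors) < 2:
                    arch = [new_dom(bn)]
                else:
                    i, j = rng.choice(len(donors), size=2, replace=False)
                    a = st_here[donors[int(i)]]["arch"]
                    b = st_here[donors[int(j)]]["arch"]
                    arch = [
                        a[int(rng.integers(len(a)))],
                        b[int(rng.integers(len(b)))],
                    ]
                    if arch[0] == arch[1]:
                        arch.append(new_dom(bn))
            # founded by one lineage that immediately duplicates, so the
            # family is observable (>= 2 members) from birth
            root = _GNode(born_at=u)
            # founding stem strictly inside the remaining branch span
            dt = min((l - u) * 0.5, 0.02) if l > u else 0.0
            root.length += dt
            c1 = _GNode(root, born_at=u + dt)
            c2 = _GNode(root, born_at=u + dt)
            if reborn is None:
                fams[fid] = _Fam(fid, bn, id(child), root, tuple(arch))
            st_here[fid] = {"tips": [c1, c2], "arch": arch}
            counts[bn]["fam_birth"] += 1
            counts[bn]["member_dup"] += 1

        # --- standalone domain gains --------------------------------------
        n_dgain = int(rng.poisson(params.dom_birth_rate * l * n_alive))
        hosts = sorted(st_here)
        for _ in range(n_dgain):
            if not hosts:
                break
            f = hosts[int(rng.integers(len(hosts)))]
            st_here[f]["arch"].append(new_dom(bn))

        # --- member duplications and deletions ----------------------------
        for fid in sorted(st_here):
            tips = st_here[fid]["tips"]
            m0 = len(tips)
            # on its birth branch a family keeps both founding copies, so
            # it stays observable as a multi-member cluster
            floor = 2 if fams[fid].birth_branch == bn else 1
            n_dup = int(rng.poisson(params.dup_rate * l * m0))
            n_del = int(rng.poisson(params.del_rate * l * m0))
            events = [(float(rng.uniform(0, l)), "dup") for _ in range(n_dup)]
            events += [(float(rng.uniform(0, l)), "del") for _ in range(n_del)]
            events.sort(key=lambda e: e[0])
            live = list(tips)
            for pos, kind in events:
                if kind == "dup":
                    t = live[int(rng.integers(len(live)))]
                    t.length += max(pos - t.born_at, 0.0)
                    at = max(pos, t.born_at)
                    c1, c2 = _GNode(t, born_at=at), _GNode(t, born_at=at)
                    live.remove(t)
                    live += [c1, c2]
                    counts[bn]["member_dup"] += 1
                else:
                    if len(live) <= floor:
                        continue  # a branch never loses its last member
                    t = live[int(rng.integers(len(live)))]
                    t.length += max(pos - t.born_at, 0.0)
                    t.dead = True
                    live.remove(t)
                    counts[bn]["member_del"] += 1
            for t in live:
                t.length += l - t.born_at
                t.born_at = 0.0
            st_here[fid]["tips"] = live

        genome_at[id(child)] = {f: tuple(s["arch"]) for f, s in st_here.items()}
        return st_here

    def recurse(node: Node, state: dict) -> None:
        for child in node.children:
            child_state = process_branch(node, child, state)
            if child.is_leaf:
                sp = child.name
                for fid in sorted(child_state):
                    s = child_state[fid]
                    leaf_arch.setdefault(fid, {})[sp] = tuple(s["arch"])
                    for i, t in enumerate(s["tips"], start=1):
                        t.name = f"{sp}_{fid}m{i}"
                        proteins.append((t.name, sp, fid))
            else:
                recurse(child, child_state)

    recurse(st.root, root_state)

    # --- emergent domain birth/death from genome differences --------------
    def dom_set(node_id: int) -> set:
        return set(d for arch in genome_at.get(node_id, {}).values() for d in arch)

    for b in st.branches():
        parent_id = id(b.parent)
        here, there = dom_set(id(b)), dom_set(parent_id)
        counts[b.canonical_name]["dom_birth"] = len(here - there)
        counts[b.canonical_name]["dom_death"] = len(there - here)
    counts[ROOT_BRANCH]["dom_birth"] = len(dom_set(id(st.root)))

    # --- prune gene trees, build newicks and distance matrices ------------
    def prune(node: _GNode) -> _GNode | None:
        if not node.children:
            return node if (node.name and not node.dead) else None
        kept = [c for c in (prune(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            kept[0].parent = node.parent
            return kept[0]
        node.children = kept
        return node

    def gnode_newick(node: _GNode) -> str:
        def rec(n: _GNode) -> str:
            if not n.children:
                return f"{n.name}:{n.length:.6f}"
            return "(" + ",".join(rec(c) for c in n.children) + f"):{n.length:.6f}"

        return rec(node) + ";"

    gene_trees: dict[str, str] = {}
    members: dict[str, list] = {}
    dist_mats: dict[str, pd.DataFrame] = {}
    rng_d = _branch_rng(seed, "distances")
    extinct = []
    for fid in sorted(fams, key=lambda f: int(f[1:])):
        root = prune(fams[fid].root)
        if root is None:
            extinct.append(fid)
            continue
        root.parent = None

        def fix_parents(n: _GNode) -> None:
            for c in n.children:
                c.parent = n
                fix_parents(c)

        fix_parents(root)
        gene_trees[fid] = gnode_newick(root)
        leaves: list[_GNode] = []

        def collect(n: _GNode) -> None:
            if not n.children:
                leaves.append(n)
            for c in n.children:
                collect(c)

        collect(root)
        members[fid] = [l.name for l in leaves]
        if len(leaves) >= 2:
            depth = {}

            def set_depth(n: _GNode, d: float) -> None:
                depth[id(n)] = d
                for c in n.children:
                    set_depth(c, d + c.length)

            set_depth(root, 0.0)
            anc: dict[int, list] = {}
            for l0 in leaves:
                chain = []
                n = l0
                while n is not None:
                    chain.append(n)
                    n = n.parent
                anc[id(l0)] = chain
            names = [l.name for l in leaves]
            d = np.zeros((len(leaves), len(leaves)))
            for i, a in enumerate(leaves):
                aset = {id(x) for x in anc[id(a)]}
                for j in range(i + 1, len(leaves)):
                    b = leaves[j]
                    n = b
                    while id(n) not in aset:
                        n = n.parent
                    dij = depth[id(a)] + depth[id(b)] - 2 * depth[id(n)]
                    if params.distance_noise_sd > 0:
                        dij = max(dij + rng_d.normal(0, params.distance_noise_sd), 0.0)
                    d[i, j] = d[j, i] = dij
            dist_mats[fid] = pd.DataFrame(d, index=names, columns=names)
    if extinct:
        warnings.warn(f"{len(extinct)} families went extinct with no trace")

    # --- similarity edges --------------------------------------------------
    rng_e = _branch_rng(seed, "edges")
    edge_rows = []
    for fid in sorted(members, key=lambda f: int(f[1:])):
        ms = members[fid]
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                if rng_e.random() >= params.drop_edge_prob:
                    edge_rows.append((ms[i], ms[j], params.intra_weight))
    all_proteins = [p for p, _, _ in proteins]
    n_false = int(rng_e.poisson(params.false_edge_prob * len(all_proteins)))
    fam_of = {p: f for p, _, f in proteins}
    for _ in range(n_false):
        a, b = rng_e.choice(len(all_proteins), size=2, replace=False)
        pa, pb = all_proteins[int(a)], all_proteins[int(b)]
        if fam_of[pa] != fam_of[pb]:
            edge_rows.append((pa, pb, params.false_weight))
    edges = pd.DataFrame(edge_rows, columns=["u", "v", "w"])

    # --- domain hits --------------------------------------------------------
    hit_rows = []
    for p, sp, fid in proteins:
        for i, dom in enumerate(leaf_arch.get(fid, {}).get(sp, ())):
            start = 1 + 200 * i
            hit_rows.append((p, dom, start, start + 149, 100.0, 1e-30))
    domain_hits = pd.DataFrame(
        hit_rows, columns=["protein", "domain", "start", "end", "score", "evalue"]
    )

    # --- truth table --------------------------------------------------------
    events = pd.DataFrame.from_dict(counts, orient="index").loc[branches]
    events.index.name = "branch"
    leaf_names = set(st.leaf_names)
    universal = [
        fid
        for fid in sorted(members, key=lambda f: int(f[1:]))
        if {p.split("_", 1)[0] for p in members[fid]} == leaf_names
    ]
    truth = GroundTruth(
        events=events,
        birth_branch={f: fams[f].birth_branch for f in members},
        death_branches={f: sorted(fams[f].death_branches) for f in members},
        gene_trees=gene_trees,
        members=members,
        architectures=leaf_arch,
        universal_families=universal,
    )
    prot_df = pd.DataFrame(proteins, columns=["protein_id", "species", "family"])
    dataset = SyntheticDataset(
        species_tree=st,
        proteins=prot_df,
        edges=edges,
        domain_hits=domain_hits,
        distance_matrices=dist_mats,
        annotations=pd.DataFrame(columns=["protein_id", "term_id"]),
        obo_text=MINI_OBO,
        truth=truth,
    )
    return dataset


def plant_enrichment(
    dataset: SyntheticDataset,
    term: str,
    branch: str,
    effect: float,
    seed: int = 0,
    base_rate: float = 0.01,
) -> SyntheticDataset:
    """Annotate families born on ``branch`` with ``term`` at probability
    ``effect``; all other families receive it at ``base_rate``.  Every
    family additionally picks up unrelated leaf terms at a low rate so
    the ontology is populated."""
    if term not in MINI_OBO:
        raise ValueError(f"term {term!r} is not in the packaged mini ontology")
    truth = dataset.truth
    known = {b.canonical_name for b in dataset.species_tree.branches()} | {ROOT_BRANCH}
    if branch not in known:
        raise ValueError(f"unknown branch {branch!r}")
    rng = _branch_rng(seed, branch, salt="plant:" + term)
    rows = []
    for fid, ms in truth.members.items():
        rep = sorted(ms)[0]  # one member carries the family annotation
        p_term = effect if truth.birth_branch[fid] == branch else base_rate
        if rng.random() < p_term:
            rows.append((rep, term))
        for other in OBO_LEAVES:
            if other != term and rng.random() < 0.10:
                rows.append((rep, other))
    ann = pd.DataFrame(rows, columns=["protein_id", "term_id"])
    return replace_dataset_annotations(dataset, ann)


def replace_dataset_annotations(
    dataset: SyntheticDataset, annotations: pd.DataFrame
) -> SyntheticDataset:
    return SyntheticDataset(
        species_tree=dataset.species_tree,
        proteins=dataset.proteins,
        edges=dataset.edges,
        domain_hits=dataset.domain_hits,
        distance_matrices=dataset.distance_matrices,
        annotations=annotations,
        obo_text=dataset.obo_text,
        truth=dataset.truth,
    )


def emit(dataset: SyntheticDataset, outdir) -> dict:
    """Write every pipeline input file plus the ground-truth JSON.

    Returns a manifest of the written paths.
    """
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "distmats").mkdir(exist_ok=True)
    paths = {}

    paths["species_tree"] = out / "species_tree.nwk"
    paths["species_tree"].write_text(write_newick(dataset.species_tree) + "\n")

    paths["proteins"] = out / "proteins.tsv"
    dataset.proteins[["protein_id", "species"]].to_csv(
        paths["proteins"], sep="\t", index=False
    )

    paths["edges"] = out / "edges.abc"
    dataset.edges.to_csv(paths["edges"], sep="\t", index=False, header=False)

    paths["domain_hits"] = out / "domains.tsv"
    dataset.domain_hits.to_csv(paths["domain_hits"], sep="\t", index=False, header=False)

    from .genetrees import write_phylip_square

    for fid, dm in dataset.distance_matrices.items():
        write_phylip_square(dm, out / "distmats" / f"{fid}.phy")
    paths["distmats"] = out / "distmats"

    paths["annotations"] = out / "annotations.tsv"
    dataset.annotations.to_csv(paths["annotations"], sep="\t", index=False)

    paths["obo"] = out / "mini.obo"
    paths["obo"].write_text(dataset.obo_text)

    truth = dataset.truth
    paths["truth"] = out / "truth.json"
    truth_doc = {
        "events": truth.events.reset_index().to_dict(orient="list"),
        "birth_branch": truth.birth_branch,
        "death_branches": truth.death_branches,
        "gene_trees": truth.gene_trees,
        "members": truth.members,
        "universal_families": truth.universal_families,
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
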