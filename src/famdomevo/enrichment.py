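"""Family-level term enrichment by the exact hypergeometric test.

Annotations are lifted from proteins to families: a term identified by
several members of one family counts once, and every family carries the
ancestor closure of its terms.  Enrichment of a target family set
against a background is the hypergeometric upper tail; depletion is the
lower tail.  Two guards against inflated discovery are applied, in this
order: an elim-style refinement that removes terms significant only
because of their significant descendants, and a permutation-based false
discovery rate built from the minimum-p distribution of random target
sets.  The conventional selection keeps terms with refined p < 0.001
and FDR < 0.1 jointly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Ontology",
    "annotate_families",
    "hypergeom_test",
    "enrich",
    "refine",
    "permutation_fdr",
    "filter_significant",
]


class Ontology:
    """A small is_a/part_of DAG of terms (child -> parent edges)."""

    def __init__(self, parents: dict[str, set[str]], names: dict[str, str] | None = None):
        self.parents = {t: set(ps) for t, ps in parents.items()}
        for ps in parents.values():
            for p in ps:
                self.parents.setdefault(p, set())
        self.names = names or {}
        self._ancestors: dict[str, frozenset[str]] = {}
        self._check_acyclic()

    @classmethod
    def from_obo(cls, path) -> "Ontology":
        import obonet

        g = obonet.read_obo(path)
        parents: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for term, data in g.nodes(data=True):
            names[term] = data.get("name", term)
            ps = set(data.get("is_a", []))
            for rel in data.get("relationship", []):
                kind, _, target = rel.partition(" ")
                if kind == "part_of":
                    ps.add(target.strip())
            parents[term] = ps
        return cls(parents, names)

    def _check_acyclic(self) -> None:
        order = self.topological_order()
        if len(order) != len(self.parents):
            raise ValueError("ontology contains a cycle")

    def topological_order(self) -> list[str]:
        """Terms ordered parents-before-children."""
        indeg = {t: len(ps) for t, ps in self.parents.items()}
        children: dict[str, list[str]] = {t: [] for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                children[p].append(t)
        ready = sorted(t for t, d in indeg.items() if d == 0)
        out = []
        while ready:
            t = ready.pop(0)
            out.append(t)
            for c in sorted(children[t]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        return out

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term``, excluding the term itself."""
        if term not in self._ancestors:
            out: set[str] = set()
            stack = list(self.parents.get(term, ()))
            while stack:
                p = stack.pop()
                if p not in out:
                    out.add(p)
                    stack.extend(self.parents.get(p, ()))
            self._ancestors[term] = frozenset(out)
        return self._ancestors[term]

    def __contains__(self, term: str) -> bool:
        return term in self.parents


def annotate_families(
    protein_terms: pd.DataFrame,
    families: dict[str, set[str]],
    dag: Ontology,
    strict: bool = False,
) -> dict[str, frozenset[str]]:
    """Family id -> ancestor-closed term set.

    ``protein_terms`` has columns protein_id, term_id.  Terms absent from
    the DAG are skipped with a warning (or raise in strict mode).  Terms
    seen in several members of one family count once — set semantics.
    """
    by_protein: dict[str, set[str]] = {}
    for p, t in zip(protein_terms["protein_id"], protein_terms["term_id"]):
        if t not in dag:
            if strict:
                raise KeyError(f"unknown term {t!r}")
            warnings.warn(f"skipping unknown term {t!r}")
            continue
        by_protein.setdefault(p, set()).add(t)
    out = {}
    for fam, members in families.items():
        terms: set[str] = set()
        for m in members:
            terms |= by_protein.get(m, set())
        closed = set(terms)
        for t in terms:
            closed |= dag.ancestors(t)
        out[fam] = frozenset(closed)
    return out


def hypergeom_test(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Exact tails for X ~ Hypergeometric(N, K, n) at the observed k.

    Returns (P(X >= k), P(X <= k)): enrichment and depletion p-values for
    k annotated items in a target of size n against K of N in the
    background.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    p_enr = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_dep = float(stats.hypergeom.cdf(k, N, K, n))
    return min(p_enr, 1.0), min(p_dep, 1.0)


def enrich(
    target: set[str],
    background: set[str],
    annotations: dict[str, frozenset[str]],
    dag: Ontology,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a family set.

    The background is the universe (must contain the target); only terms
    annotated to at least one background family are tested.
    """
    if not target <= background:
        raise ValueError("target must be a subset of the background")
    N = len(background)
    n = len(target)
    term_bg: dict[str, int] = {}
    term_tg: dict[str, int] = {}
    for fam in background:
        for t in annotations.get(fam, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
            if fam in target:
                term_tg[t] = term_tg.get(t, 0) + 1
    rows = []
    for t in sorted(term_bg):
        K = term_bg[t]
        k = term_tg.get(t, 0)
        p_enr, p_dep = hypergeom_test(k, n, K, N)
        rows.append((t, dag.names.get(t, t), k, n, K, N, p_enr, p_dep))
    return pd.DataFrame(
        rows, columns=["term", "name", "k", "n", "K", "N", "p_enriched", "p_depleted"]
    )


def refine(
    results: pd.DataFrame,
    dag: Ontology,
    annotations: dict[str, frozenset[str]],
    target: set[str],
    background: set[str],
    threshold: float = 0.001,
) -> pd.DataFrame:
    """Elim-style refinement: strip terms significant only through their
    significant descendants.

    Terms are visited leaves-first.  When a term is significant at
    ``threshold`` (after its own refinement), the target families it
    annotates are eliminated from the counts of all its ancestors before
    those are re-tested.  The output adds ``p_refined`` and
    ``refined_out`` (significant before, not after).
    """
    res = results.set_index("term")
    N = int(res["N"].iloc[0]) if len(res) else len(background)
    n = int(res["n"].iloc[0]) if len(res) else len(target)
    fams_with_term: dict[str, set[str]] = {}
    for fam in background:
        for t in annotations.get(fam, ()):
            fams_with_term.setdefault(t, set()).add(fam)
    eliminated: dict[str, set[str]] = {t: set() for t in res.index}
    p_refined = {}
    refined_out = {}
    for term in reversed(dag.topological_order()):
        if term not in res.index:
            continue
        bg_f = fams_with_term.get(term, set())
        elim = eliminated[term]
        k = len((bg_f & target) - elim)
        K = len(bg_f - elim)
        p, _ = hypergeom_test(k, n, K, N)
        p_refined[term] = p
        refined_out[term] = bool(res.loc[term, "p_enriched"] < threshold and p >= threshold)
        if p < threshold:
            drop = bg_f & target
            for anc in dag.ancestors(term):
                if anc in eliminated:
                    eliminated[anc] |= drop
    out = results.copy()
    out["p_refined"] = out["term"].map(p_refined)
    out["refined_out"] = out["term"].map(refined_out)
    return out


def permutation_fdr(
    results: pd.DataFrame,
    target_size: int,
    background: set[str],
    annotations: dict[str, frozenset[str]],
    dag: Ontology,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Min-p permutation FDR: the fraction of random same-size targets
    whose best enrichment p is at least as small as each observed p.

    Deterministic for a fixed seed.  ``reps`` below 100 only warns.
    """
    if reps < 100:
        warnings.warn(f"permutation FDR with reps={reps} < 100 is unreliable")
    rng = np.random.default_rng(seed)
    bg = sorted(background)
    N = len(bg)
    terms = sorted({t for f in bg for t in annotations.get(f, ())})
    tindex = {t: i for i, t in enumerate(terms)}
    member = np.zeros((len(terms), N), dtype=np.int64)
    for j, fam in enumerate(bg):
        for t in annotations.get(fam, ()):
            member[tindex[t], j] = 1
    K = member.sum(axis=1)
    min_p = np.empty(reps)
    for rep in range(reps):
        idx = rng.choice(N, size=target_size, replace=False)
        k = member[:, idx].sum(axis=1)
        p = stats.hypergeom.sf(k - 1, N, K, target_size)
        min_p[rep] = p.min() if len(p) else 1.0
    pcol = "p_refined" if "p_refined" in results.columns else "p_enriched"
    out = results.copy()
    out["fdr"] = [
        float((min_p <= p).mean()) for p in out[pcol]
    ]
    return out


def filter_significant(
    results: pd.DataFrame, p_max: float = 0.001, fdr_max: float = 0.1
) -> pd.DataFrame:
    """Joint selection: refined p below ``p_max`` and FDR below ``fdr_max``."""
    pcol = "p_refined" if "p_refined" in results.columns else "p_enriched"
    keep = (results[pcol] < p_max) & (results["fdr"] < fdr_max)
    return results.loc[keep].reset_index(drop=True)
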