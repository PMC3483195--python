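import itertools

import numpy as np
import pandas as pd
import pytest

from famdomevo import enrichment as E


@pytest.fixture
def dag():
    return E.Ontology(
        parents={
            "root": set(),
            "mid": {"root"},
            "leafA": {"mid"},
            "leafB": {"mid"},
            "other": {"root"},
        },
        names={"root": "root", "mid": "mid"},
    )


class TestOntology:
    def test_ancestors(self, dag):
        assert dag.ancestors("leafA") == {"mid", "root"}
        assert dag.ancestors("root") == frozenset()

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            E.Ontology({"a": {"b"}, "b": {"a"}})

    def test_from_obo(self, mini_obo_path):
        dag = E.Ontology.from_obo(mini_obo_path)
        assert "T:0101" in dag
        assert dag.ancestors("T:0101") == {"T:0100", "T:0001"}
        assert dag.names["T:0100"] == "signaling"


class TestAnnotateFamilies:
    def test_terms_deduplicated_within_family(self, dag):
        pt = pd.DataFrame(
            {"protein_id": ["p1", "p2", "p3"], "term_id": ["leafA"] * 3}
        )
        out = E.annotate_families(pt, {"f1": {"p1", "p2", "p3"}}, dag)
        assert out["f1"] == {"leafA", "mid", "root"}

    def test_ancestor_closure(self, dag):
        pt = pd.DataFrame({"protein_id": ["p1"], "term_id": ["leafB"]})
        out = E.annotate_families(pt, {"f1": {"p1"}}, dag)
        assert {"mid", "root"} <= out["f1"]

    def test_unannotated_family_empty(self, dag):
        out = E.annotate_families(
            pd.DataFrame(columns=["protein_id", "term_id"]), {"f1": {"p1"}}, dag
        )
        assert out["f1"] == frozenset()

    def test_unknown_term_skipped_or_strict(self, dag):
        pt = pd.DataFrame({"protein_id": ["p1"], "term_id": ["nope"]})
        with pytest.warns(UserWarning):
            out = E.annotate_families(pt, {"f1": {"p1"}}, dag)
        assert out["f1"] == frozenset()
        with pytest.raises(KeyError):
            E.annotate_families(pt, {"f1": {"p1"}}, dag, strict=True)


class TestHypergeom:
    def test_small_exact_value(self):
        p_enr, _ = E.hypergeom_test(k=2, n=2, K=2, N=5)
        assert p_enr == pytest.approx(0.1)

    def test_k_zero_enrichment_is_one(self):
        p_enr, _ = E.hypergeom_test(k=0, n=3, K=2, N=10)
        assert p_enr == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            E.hypergeom_test(k=3, n=2, K=2, N=5)

    def test_matches_enumeration_oracle(self):
        """Exact tails agree with brute-force enumeration of all draws
        for every consistent configuration with N <= 9."""
        for N in range(1, 10):
            universe = list(range(N))
            for K in range(N + 1):
                marked = set(universe[:K])
                for n in range(N + 1):
                    draws = list(itertools.combinations(universe, n))
                    counts = [len(marked & set(d)) for d in draws]
                    for k in set(counts):
                        ge = sum(c >= k for c in counts) / len(draws)
                        le = sum(c <= k for c in counts) / len(draws)
                        p_enr, p_dep = E.hypergeom_test(k, n, K, N)
                        assert p_enr == pytest.approx(ge, abs=1e-12)
                        assert p_dep == pytest.approx(le, abs=1e-12)


def _setup_refinement_case():
    """A 3-term chain where the parent is significant only through the
    leaf's families."""
    dag = E.Ontology({"root": set(), "parent": {"root"}, "child": {"parent"}})
    background = {f"f{i}" for i in range(200)}
    target = {f"f{i}" for i in range(10)}
    annotations = {}
    for f in background:
        terms = set()
        i = int(f[1:])
        if i < 10:  # all target families carry the child term
            terms = {"child", "parent", "root"}
        elif i < 20:
            terms = {"parent", "root"}
        annotations[f] = frozenset(terms)
    return dag, background, target, annotations


class TestRefine:
    def test_parent_driven_by_child_refined_out(self):
        dag, background, target, ann = _setup_refinement_case()
        res = E.enrich(target, background, ann, dag)
        res = E.refine(res, dag, ann, target, background)
        res = res.set_index("term")
        assert res.loc["child", "p_enriched"] < 0.001
        assert not res.loc["child", "refined_out"]
        assert res.loc["parent", "p_enriched"] < 0.001
        assert res.loc["parent", "refined_out"]

    def test_flat_dag_identity(self):
        dag = E.Ontology({"a": set(), "b": set()})
        background = {f"f{i}" for i in range(50)}
        target = {f"f{i}" for i in range(5)}
        ann = {f: frozenset({"a"} if int(f[1:]) < 5 else {"b"}) for f in background}
        res = E.enrich(target, background, ann, dag)
        refined = E.refine(res, dag, ann, target, background)
        assert (refined["p_refined"] == refined["p_enriched"]).all()
        assert not refined["refined_out"].any()

    def test_term_without_significant_descendants_unchanged(self):
        dag, background, target, ann = _setup_refinement_case()
        res = E.enrich(target, background, ann, dag)
        refined = E.refine(res, dag, ann, target, background).set_index("term")
        # root annotates only the same 20 families; its own p is weak and
        # unchanged by elimination of an insignificant... child drives all:
        assert refined.loc["child", "p_refined"] == pytest.approx(
            refined.loc["child", "p_enriched"]
        )


class TestPermutationFDR:
    def _toy(self):
        dag = E.Ontology({"a": set(), "b": set()})
        background = {f"f{i}" for i in range(60)}
        ann = {
            f: frozenset({"a"} if int(f[1:]) % 3 == 0 else {"b"})
            for f in background
        }
        target = {f"f{i}" for i in range(0, 30, 3)}
        res = E.enrich(target, background, ann, dag)
        return dag, background, ann, target, res

    def test_deterministic_given_seed(self):
        dag, background, ann, target, res = self._toy()
        f1 = E.permutation_fdr(res, len(target), background, ann, dag, reps=200, seed=9)
        f2 = E.permutation_fdr(res, len(target), background, ann, dag, reps=200, seed=9)
        assert list(f1["fdr"]) == list(f2["fdr"])

    def test_low_reps_warns(self):
        dag, background, ann, target, res = self._toy()
        with pytest.warns(UserWarning):
            E.permutation_fdr(res, len(target), background, ann, dag, reps=50, seed=1)

    def test_null_p_values_super_uniform(self):
        """Random target sets: P(p <= t) <= t (within sampling error)."""
        rng = np.random.default_rng(12)
        dag = E.Ontology({f"t{i}": set() for i in range(6)})
        background = {f"f{i}" for i in range(120)}
        ann = {
            f: frozenset({f"t{rng.integers(6)}"} | ({f"t{rng.integers(6)}"} if rng.random() < 0.4 else set()))
            for f in sorted(background)
        }
        ps = []
        bg = sorted(background)
        for _ in range(200):
            tgt = set(rng.choice(bg, size=25, replace=False))
            ps.extend(E.enrich(tgt, background, ann, dag)["p_enriched"])
        ps = np.asarray(ps)
        for t in (0.01, 0.05, 0.1, 0.25):
            assert (ps <= t).mean() <= t + 0.02


class TestFilterSignificant:
    def _frame(self, p, fdr):
        return pd.DataFrame({"term": ["x"], "p_refined": [p], "fdr": [fdr]})

    def test_joint_thresholds(self):
        assert len(E.filter_significant(self._frame(0.0005, 0.05))) == 1
        assert len(E.filter_significant(self._frame(0.0005, 0.2))) == 0
        assert len(E.filter_significant(self._frame(0.005, 0.05))) == 0

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["term", "p_refined", "fdr"])
        assert len(E.filter_significant(empty)) == 0
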