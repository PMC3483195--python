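import itertools
import random

import numpy as np
import pandas as pd
import pytest

from famdomevo import dollo
from famdomevo.trees import parse_newick

from _oracles import all_rooted_trees, dollo_oracle, random_rooted_tree


class TestPresenceMatrix:
    TAXA = ["Hsa", "Mmu", "Cel"]

    def test_binary_rows(self):
        m = dollo.presence_matrix({"f1": {"Hsa", "Cel"}}, self.TAXA)
        assert list(m.loc["f1"]) == [1, 0, 1]

    def test_empty_character_rejected(self):
        with pytest.raises(ValueError, match="no taxon"):
            dollo.presence_matrix({"f1": set()}, self.TAXA)

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            dollo.presence_matrix({"f1": {"Xxx"}}, self.TAXA)


class TestDolloReconstruct:
    def test_present_everywhere_root_birth_no_loss(self):
        t = parse_newick("((A,B),(C,D));")
        birth, losses = dollo.dollo_reconstruct({"A", "B", "C", "D"}, t)
        assert birth == dollo.ROOT_BRANCH and losses == set()

    def test_single_taxon_pendant_birth(self):
        t = parse_newick("((A,B),(C,D));")
        birth, losses = dollo.dollo_reconstruct({"C"}, t)
        assert birth == "C" and losses == set()

    def test_two_losses_example(self):
        t = parse_newick("(((A,B),C),(D,E));")
        birth, losses = dollo.dollo_reconstruct({"A", "B", "D"}, t)
        assert birth == dollo.ROOT_BRANCH
        assert losses == {"C", "E"}

    def test_all_absent_raises(self):
        t = parse_newick("(A,B);")
        with pytest.raises(ValueError):
            dollo.dollo_reconstruct(set(), t)

    def test_matches_exhaustive_single_gain_oracle(self):
        """Every rooted binary tree with <= 6 leaves, every non-empty
        character: the (birth, losses) pair attains the single-gain
        minimum computed by exhaustive gain placement."""
        for n in range(2, 7):
            labels = [f"L{i}" for i in range(n)]
            for tree in all_rooted_trees(labels):
                for bits in range(1, 2**n):
                    present = {labels[i] for i in range(n) if bits >> i & 1}
                    birth, losses = dollo.dollo_reconstruct(present, tree)
                    node, o_losses, o_count = dollo_oracle(present, tree)
                    assert len(losses) == o_count
                    assert losses == o_losses
                    expected = (
                        dollo.ROOT_BRANCH
                        if node is tree.root
                        else node.canonical_name
                    )
                    assert birth == expected


class TestCountEvents:
    def test_universal_characters(self):
        t = parse_newick("((A,B),C);")
        m = dollo.presence_matrix(
            {f"f{i}": {"A", "B", "C"} for i in range(3)}, ["A", "B", "C"]
        )
        ev = dollo.count_events(m, t)
        assert ev.loc[dollo.ROOT_BRANCH, "birth"] == 3
        assert ev["death"].sum() == 0

    def test_additivity_of_unions(self):
        t = parse_newick("(((A,B),C),(D,E));")
        taxa = list("ABCDE")
        m1 = dollo.presence_matrix({"u1": set(taxa)}, taxa)
        m2 = dollo.presence_matrix({"x1": {"A", "B", "D"}}, taxa)
        both = dollo.presence_matrix(
            {"u1": set(taxa), "x1": {"A", "B", "D"}}, taxa
        )
        total = dollo.count_events(both, t)
        summed = dollo.count_events(m1, t) + dollo.count_events(m2, t)
        pd.testing.assert_frame_equal(total, summed)

    def test_birth_sum_equals_character_count(self):
        rng = random.Random(5)
        taxa = [f"T{i}" for i in range(8)]
        t = random_rooted_tree(taxa, rng)
        chars = {}
        for i in range(120):
            k = rng.randint(1, 8)
            chars[f"c{i}"] = set(rng.sample(taxa, k))
        m = dollo.presence_matrix(chars, taxa)
        ev = dollo.count_events(m, t)
        assert ev["birth"].sum() == len(chars)


class TestClassifyFamily:
    ALL = {"Hsa", "Mmu", "Gga", "Dme", "Aae", "Bmo", "Cel", "Cbr", "Tsp", "Sce", "Mbr"}

    def test_universal(self):
        assert dollo.classify_family(set(self.ALL)) == "universal"

    def test_single_species_within_clade(self):
        assert dollo.classify_family({"Tsp"}) == "clade_specific_single_species"

    def test_shared_within_clade(self):
        assert dollo.classify_family({"Cel", "Cbr"}) == "clade_specific_shared"

    def test_cross_clade_is_other(self):
        assert dollo.classify_family({"Cel", "Hsa"}) == "other"

    def test_exhaustive_partition(self):
        """Categories are exhaustive and mutually exclusive over all
        non-empty metazoan subsets of a reduced taxon set."""
        taxa = ["Hsa", "Gga", "Cel", "Tsp", "Dme"]
        for r in range(1, len(taxa) + 1):
            for sub in itertools.combinations(taxa, r):
                cat = dollo.classify_family(set(sub))
                assert cat in {
                    "universal",
                    "clade_specific_single_species",
                    "clade_specific_shared",
                    "other",
                }


class TestUniqueLosses:
    def test_single_zero_counts(self):
        taxa = [f"T{i}" for i in range(11)]
        m = pd.DataFrame(1, index=["c1", "c2", "c3"], columns=taxa)
        m.loc["c1", "T3"] = 0
        m.loc["c2", "T3"] = 0
        m.loc["c2", "T5"] = 0  # two zeros: counts nowhere
        out = dollo.unique_losses(m)
        assert out["T3"] == 1
        assert out.sum() == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        taxa = [f"T{i}" for i in range(11)]
        m = pd.DataFrame(
            rng.integers(0, 2, size=(100, 11)), columns=taxa,
            index=[f"c{i}" for i in range(100)],
        )
        m.iloc[:, 0] |= (m.sum(axis=1) == 0).astype(int)  # no empty rows
        out = dollo.unique_losses(m)
        for j, t in enumerate(taxa):
            expect = sum(
                1
                for i in range(100)
                if m.iloc[i, j] == 0 and (m.iloc[i] == 0).sum() == 1
            )
            assert out[t] == expect


class TestDomainOverlap:
    def test_set_intersections(self):
        out = dollo.new_family_domain_overlap(
            birth_assignments={"f1": "X", "f2": "X", "f3": "Y"},
            family_domains={"f1": {"d1"}, "f2": {"d2"}, "f3": {"d3"}, "u1": {"d2", "d4"}},
            universal_families={"u1"},
            branches=["X", "Y"],
        )
        assert out["sizes"] == {"X": 2, "Y": 1}
        assert out["universal_overlap"] == {"X": 1, "Y": 0}
        assert out["pairwise_overlap"][("X", "Y")] == 0

    def test_disjoint_sets(self):
        out = dollo.new_family_domain_overlap(
            {"f1": "X"}, {"f1": {"d1"}, "u1": {"d9"}}, {"u1"}, ["X"]
        )
        assert out["universal_overlap"]["X"] == 0
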