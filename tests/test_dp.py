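import math

import pytest

import adjforest as af
from adjforest import io as afio
from adjforest.dp import PairScheme

from conftest import small_instances


class TestTables:
    def test_extant_leaf_case(self, fixture1):
        _, inst = fixture1
        t = af.compute_tables(inst, algebra="min-plus")
        assert t.root_values() == (0.0, math.inf)

    def test_speciation_case(self, fixture2):
        _, inst = fixture2
        t = af.compute_tables(inst, algebra="min-plus")
        assert t.root_values() == (0.0, 2.0)

    def test_duplication_case(self, fixture3):
        _, inst = fixture3
        t = af.compute_tables(inst, algebra="min-plus")
        assert t.root_values() == (0.0, 1.0)

    def test_only_equal_species_pairs_present(self, figure1_instance):
        _, inst = figure1_instance
        scheme = PairScheme(inst)
        assert all(g1.species is g2.species for g1, g2 in scheme.pairs)
        assert len(scheme.pairs) <= len(inst.g1.nodes) * len(inst.g2.nodes)

    def test_parsimony_score_requires_min_plus(self, fixture2):
        _, inst = fixture2
        t = af.compute_tables(inst, algebra="sum-times",
                              params=af.EnsembleParams(kT=1.0))
        with pytest.raises(af.ModelError):
            af.parsimony_score(t)


class TestBacktrack:
    def test_single_extant_adjacency(self, fixture1):
        _, inst = fixture1
        t = af.compute_tables(inst, algebra="min-plus")
        forest = af.backtrack_optimal(t, inst)
        assert forest.serialize() == "a1|a2|Extant"

    def test_speciation_forest(self, fixture2):
        _, inst = fixture2
        t = af.compute_tables(inst, algebra="min-plus")
        forest = af.backtrack_optimal(t, inst)
        assert len(forest.roots) == 1
        root = forest.roots[0]
        assert root.event == "Spec" and not root.is_root_gain
        assert sorted(c.event for c in root.children) == ["Extant", "Extant"]

    def test_duplication_forest_has_no_break(self, fixture3):
        _, inst = fixture3
        t = af.compute_tables(inst, algebra="min-plus")
        forest = af.backtrack_optimal(t, inst)
        assert forest.serialize() == "(a1|a2|Extant)v|a2|GDup"
        assert forest.n_breaks() == 0

    def test_backtrack_is_deterministic(self, figure1_instance):
        _, inst = figure1_instance
        t = af.compute_tables(inst, algebra="min-plus")
        f1 = af.backtrack_optimal(t, inst)
        f2 = af.backtrack_optimal(t, inst)
        assert f1.serialize() == f2.serialize()

    def test_backtrack_achieves_optimum_and_validates(self):
        for _, inst, _ in small_instances(25):
            t = af.compute_tables(inst, algebra="min-plus")
            forest = af.backtrack_optimal(t, inst)
            assert af.score_forest(forest) == af.parsimony_score(t)
            assert af.validate_forest_against_instance(forest, inst) == []


class TestOracleEquivalence:
    def test_parsimony_matches_enumeration(self):
        for _, inst, _ in small_instances(40):
            t = af.compute_tables(inst, algebra="min-plus")
            space = af.enumerate_forests(inst)
            assert af.parsimony_score(t) == space.min_score()

    def test_kappa_is_homogeneous(self):
        """Every alternative of every pair yields the same rescaling-factor
        count (asserted inside compute_kappa)."""
        for _, inst, _ in small_instances(20):
            scheme = PairScheme(inst)
            kappa = scheme.compute_kappa()
            assert all(k >= 0 for k in kappa)


class TestBuildInstances:
    SP = "(A,B)R;"
    T1 = ("(a1[&&NHX:S=A:Ev=Extant],b1[&&NHX:S=B:Ev=Extant])"
          "r1[&&NHX:S=R:Ev=Spec];")
    T2 = ("(a2[&&NHX:S=A:Ev=Extant],b2[&&NHX:S=B:Ev=Extant])"
          "r2[&&NHX:S=R:Ev=Spec];")
    T3 = ("(a3[&&NHX:S=A:Ev=Extant],b3[&&NHX:S=B:Ev=Extant])"
          "r3[&&NHX:S=R:Ev=Spec];")

    def trees(self, *texts):
        species = afio.parse_species_tree(self.SP)
        return species, afio.parse_reconciled_gene_trees("\n".join(texts),
                                                         species)

    def test_one_pair_one_instance(self):
        _, trees = self.trees(self.T1, self.T2)
        adj = afio.parse_adjacencies("a1\ta2\n", trees)
        assert len(af.build_instances(trees, adj)) == 1

    def test_two_linked_pairs_two_instances(self):
        _, trees = self.trees(self.T1, self.T2, self.T3)
        adj = afio.parse_adjacencies("a1\ta2\na1\ta3\n", trees)
        assert len(af.build_instances(trees, adj)) == 2

    def test_same_tree_cross_species_pair_rejected_at_parse(self):
        _, trees = self.trees(self.T1)
        with pytest.raises(af.ModelError):
            afio.parse_adjacencies("a1\tb1\n", trees)

    def test_self_instance_matches_oracle_semantics(self):
        species = afio.parse_species_tree("A;")
        trees = afio.parse_reconciled_gene_trees(
            "(x1[&&NHX:S=A:Ev=Extant],x2[&&NHX:S=A:Ev=Extant])"
            "v[&&NHX:S=A:Ev=GDup];", species)
        adj = afio.parse_adjacencies("x1\tx2\n", trees)
        instances = af.build_instances(trees, adj)
        assert len(instances) == 1
        inst = instances[0]
        assert inst.g2 is not inst.g1
        t = af.compute_tables(inst, algebra="min-plus")
        space = af.enumerate_forests(inst)
        assert af.parsimony_score(t) == space.min_score()
        count = sum(af.compute_tables(inst, algebra="counting").root_values())
        assert count == len(space)

    def test_unplaceable_adjacency_rejected(self):
        _, trees = self.trees(self.T1)
        orphan = af.ExtantAdjacencySet()
        orphan.add("a1", "zz")
        with pytest.raises(af.ModelError):
            af.build_instances(trees, orphan)
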