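import pytest

import adjforest as af
from adjforest import io as afio


def make_instance(species_newick: str, tree_lines: str, adjacency_text: str):
    """Build a DecoInstance from NHX text fixtures."""
    species = afio.parse_species_tree(species_newick)
    trees = afio.parse_reconciled_gene_trees(tree_lines, species)
    adjacencies = afio.parse_adjacencies(adjacency_text, trees)
    instances = af.build_instances(trees, adjacencies)
    assert len(instances) == 1
    return species, instances[0]


@pytest.fixture
def fixture1():
    """Two single-gene families in one extant species, one adjacency."""
    return make_instance(
        "A;",
        "a1[&&NHX:S=A:Ev=Extant];\na2[&&NHX:S=A:Ev=Extant];",
        "a1\ta2\n",
    )


@pytest.fixture
def fixture2():
    """Two speciation-rooted families over (A,B)R with both descendant
    adjacencies conserved."""
    return make_instance(
        "(A,B)R;",
        "(a1[&&NHX:S=A:Ev=Extant],b1[&&NHX:S=B:Ev=Extant])"
        "r1[&&NHX:S=R:Ev=Spec];\n"
        "(a2[&&NHX:S=A:Ev=Extant],b2[&&NHX:S=B:Ev=Extant])"
        "r2[&&NHX:S=R:Ev=Spec];",
        "a1\ta2\nb1\tb2\n",
    )


@pytest.fixture
def fixture3():
    """A duplicated family against a single gene, single adjacency."""
    return make_instance(
        "A;",
        "(a1[&&NHX:S=A:Ev=Extant],a1b[&&NHX:S=A:Ev=Extant])"
        "v[&&NHX:S=A:Ev=GDup];\n"
        "a2[&&NHX:S=A:Ev=Extant];",
        "a1\ta2\n",
    )


@pytest.fixture
def figure1_instance():
    """The worked two-species example: a duplicated family against a
    post-speciation duplicated family, four conserved extant adjacencies."""
    return make_instance(
        "(A,B)C;",
        "((A1[&&NHX:S=A:Ev=Extant],B1[&&NHX:S=B:Ev=Extant])"
        "u1[&&NHX:S=C:Ev=Spec],"
        "(A2[&&NHX:S=A:Ev=Extant],B2[&&NHX:S=B:Ev=Extant])"
        "u2[&&NHX:S=C:Ev=Spec])r1[&&NHX:S=C:Ev=GDup];\n"
        "((A3[&&NHX:S=A:Ev=Extant],A4[&&NHX:S=A:Ev=Extant])"
        "vA[&&NHX:S=A:Ev=GDup],"
        "(B3[&&NHX:S=B:Ev=Extant],B4[&&NHX:S=B:Ev=Extant])"
        "vB[&&NHX:S=B:Ev=GDup])r2[&&NHX:S=C:Ev=Spec];",
        "A1\tA3\nB1\tB3\nA2\tA4\nB2\tB4\n",
    )


def small_instances(n, start_seed=0, **overrides):
    """Simulated instances with gene trees small enough to enumerate."""
    out = []
    seed = start_seed
    while len(out) < n:
        params = af.SimulationParams(seed=seed, **overrides)
        out.append(af.simulate_instance(params))
        seed += 1
    return out


def enumerable_instances(n, start_seed=0, max_count=500_000, **overrides):
    """(instance, forest-space) pairs, skipping the rare draws whose forest
    space exceeds the enumeration budget."""
    out = []
    seed = start_seed
    while len(out) < n:
        params = af.SimulationParams(seed=seed, **overrides)
        seed += 1
        _, inst, _ = af.simulate_instance(params)
        try:
            space = af.enumerate_forests(inst, max_count=max_count)
        except af.ForestSpaceOverflow:
            continue
        out.append((inst, space))
    return out
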