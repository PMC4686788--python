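"""Core domain types: species trees, reconciled gene trees, adjacencies and
adjacency forests.

The model follows the DeCo framework: a rooted binary species tree anchors
reconciled gene trees whose nodes carry a species assignment ``s(g)`` and an
event ``e(g)`` (speciation, gene duplication, gene loss, extant gene).  The
evolution of a gene adjacency — an unordered pair of genes consecutive on a
chromosome — is described by an adjacency forest whose nodes are pairs of
gene-tree nodes, with adjacency-specific events (adjacency duplication, loss,
break, and gains attached to tree roots).  The parsimony score of a forest is
the weighted number of adjacency gains and breaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

# Gene-level events
SPEC = "Spec"
GDUP = "GDup"
GLOSS = "GLoss"
EXTANT = "Extant"
# Adjacency-specific events
ADUP = "ADup"
ALOSS = "ALoss"
ABREAK = "ABreak"

GENE_LEAF_EVENTS = {EXTANT, GLOSS}
GENE_INTERNAL_EVENTS = {SPEC, GDUP}
ADJ_LEAF_EVENTS = {EXTANT, GLOSS, ALOSS, ABREAK}
ADJ_INTERNAL_EVENTS = {SPEC, GDUP, ADUP}


class ModelError(ValueError):
    """A structural invariant of the model is violated."""


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class SpeciesNode:
    __slots__ = ("label", "parent", "children", "index", "_last")

    def __init__(self, label: str):
        self.label = label
        self.parent: SpeciesNode | None = None
        self.children: list[SpeciesNode] = []
        self.index = -1      # preorder index
        self._last = -1      # highest preorder index in the subtree

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"SpeciesNode({self.label})"


class SpeciesTree:
    """Rooted binary phylogeny of genomes.

    Every internal node has exactly two children; labels are unique and
    required on all nodes so that reconciliation annotations can refer to
    internal species.
    """

    def __init__(self, root: SpeciesNode):
        self.root = root
        self.by_label: dict[str, SpeciesNode] = {}
        self._index()
        self._validate()

    def _index(self) -> None:
        counter = 0
        stack = [self.root]
        order: list[SpeciesNode] = []
        while stack:
            node = stack.pop()
            node.index = counter
            counter += 1
            order.append(node)
            stack.extend(reversed(node.children))
        for node in reversed(order):
            node._last = node.index if node.is_leaf else max(c._last for c in node.children)

    def _validate(self) -> None:
        for node in self.preorder():
            if node.label is None or node.label == "":
                raise ModelError("species tree node without a label")
            if node.label in self.by_label:
                raise ModelError(f"duplicate species label {node.label!r}")
            self.by_label[node.label] = node
            if node.children and len(node.children) != 2:
                raise ModelError(
                    f"species tree node {node.label!r} has {len(node.children)} "
                    "children; the tree must be binary"
                )

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[SpeciesNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def __contains__(self, label: str) -> bool:
        return label in self.by_label

    def __getitem__(self, label: str) -> SpeciesNode:
        try:
            return self.by_label[label]
        except KeyError:
            raise ModelError(f"unknown species label {label!r}") from None

    def is_descendant_or_equal(self, a: SpeciesNode, b: SpeciesNode) -> bool:
        """True iff ``a`` lies in the subtree rooted at ``b``."""
        return b.index <= a.index <= b._last

    def lca(self, a: SpeciesNode, b: SpeciesNode) -> SpeciesNode:
        while not (a.index <= b.index <= a._last):
            a = a.parent
            if a is None:  # pragma: no cover - root covers everything
                raise ModelError("disconnected species nodes")
        return a


# ---------------------------------------------------------------------------
# Reconciled gene trees
# ---------------------------------------------------------------------------

class GeneNode:
    """A node of a reconciled gene tree: a gene ``g`` with species ``s(g)``
    and event ``e(g)``."""

    __slots__ = ("label", "species", "event", "children", "parent", "index")

    def __init__(self, label: str, species: SpeciesNode, event: str,
                 children: list["GeneNode"] | None = None):
        self.label = label
        self.species = species
        self.event = event
        self.children: list[GeneNode] = children or []
        self.parent: GeneNode | None = None
        self.index = -1  # preorder index within its tree
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"GeneNode({self.label}, {self.species.label}, {self.event})"


class ReconciledGeneTree:
    """A gene-family tree whose nodes all carry valid species/event
    annotations with respect to a species tree."""

    def __init__(self, root: GeneNode, species_tree: SpeciesTree):
        self.root = root
        self.species_tree = species_tree
        self.nodes: list[GeneNode] = []
        stack = [root]
        while stack:
            node = stack.pop()
            node.index = len(self.nodes)
            self.nodes.append(node)
            stack.extend(reversed(node.children))
        problems = validate_gene_tree(self, species_tree)
        if problems:
            raise ModelError("invalid reconciled gene tree: " + "; ".join(problems))

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes if n.is_leaf)

    def leaves(self) -> list[GeneNode]:
        return [n for n in self.nodes if n.is_leaf]

    def extant_leaves(self) -> list[GeneNode]:
        return [n for n in self.nodes if n.event == EXTANT]

    def postorder(self):
        def walk(node):
            for c in node.children:
                yield from walk(c)
            yield node
        yield from walk(self.root)

    def copy(self) -> "ReconciledGeneTree":
        def clone(node: GeneNode) -> GeneNode:
            return GeneNode(node.label, node.species, node.event,
                            [clone(c) for c in node.children])
        return ReconciledGeneTree(clone(self.root), self.species_tree)


def validate_gene_tree(tree: "ReconciledGeneTree | GeneNode",
                       species_tree: SpeciesTree) -> list[str]:
    """Check every GeneNode invariant; returns a list of violations."""
    root = tree.root if isinstance(tree, ReconciledGeneTree) else tree
    problems: list[str] = []
    seen_labels: set[str] = set()
    stack = [root]
    while stack:
        g = stack.pop()
        if g.label in seen_labels:
            problems.append(f"duplicate gene label {g.label!r}")
        seen_labels.add(g.label)
        if g.is_leaf:
            if g.event not in GENE_LEAF_EVENTS:
                problems.append(f"leaf {g.label!r} has internal event {g.event}")
            continue
        if len(g.children) != 2:
            problems.append(f"internal node {g.label!r} has {len(g.children)} children")
            stack.extend(g.children)
            continue
        a, b = g.children
        if g.event == SPEC:
            want = {c.label for c in g.species.children}
            got = {a.species.label, b.species.label}
            if want != got:
                problems.append(
                    f"Spec node {g.label!r}: children map to {sorted(got)}, "
                    f"expected the species children {sorted(want)}"
                )
        elif g.event == GDUP:
            if not (a.species is g.species and b.species is g.species):
                problems.append(
                    f"GDup node {g.label!r}: children species "
                    f"{{{a.species.label}, {b.species.label}}} != {g.species.label}"
                )
        else:
            problems.append(f"internal node {g.label!r} has leaf event {g.event}")
        for c in (a, b):
            if not species_tree.is_descendant_or_equal(c.species, g.species):
                problems.append(
                    f"child {c.label!r} species {c.species.label} is not a "
                    f"descendant of parent species {g.species.label}"
                )
        stack.extend(g.children)
    return problems


# ---------------------------------------------------------------------------
# Adjacencies
# ---------------------------------------------------------------------------

class ExtantAdjacencySet:
    """Deduplicated set of unordered pairs of extant gene labels.

    Gene orientation is not modelled; both members of a pair must be extant
    genes of the same species.
    """

    def __init__(self, pairs: set[frozenset[str]] | None = None):
        self.pairs: set[frozenset[str]] = set(pairs or set())

    def add(self, label1: str, label2: str) -> None:
        if label1 == label2:
            raise ModelError(f"self-adjacency {label1!r}")
        self.pairs.add(frozenset((label1, label2)))

    def __contains__(self, pair) -> bool:
        a, b = pair
        return frozenset((a, b)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        for pair in sorted(self.pairs, key=sorted):
            yield tuple(sorted(pair))


@dataclass(frozen=True)
class CostParams:
    """Penalties for the two scored adjacency events."""
    ag: float = 1.0   # adjacency gain
    ab: float = 1.0   # adjacency break

    def __post_init__(self):
        if self.ag < 0 or self.ab < 0:
            raise ModelError("adjacency gain/break penalties must be nonnegative")


@dataclass(frozen=True)
class EnsembleParams:
    """Boltzmann-ensemble configuration: pseudo-temperature and rescaling factor.

    ``kT`` controls how sharply the distribution concentrates on parsimonious
    forests (kT->0: uniform over co-optimal forests; kT->inf: uniform over the
    whole space).  ``alpha`` is the homogeneous rescaling factor used to keep
    partition-function values within floating range; it does not affect any
    probability.
    """
    kT: float = 0.1
    alpha: float = 1.0

    def __post_init__(self):
        if self.kT <= 0:
            raise ModelError("kT must be positive")
        if self.alpha <= 0:
            raise ModelError("alpha must be positive")


class DecoInstance:
    """A pair of reconciled gene trees plus the extant adjacencies linking
    leaves of the first tree to leaves of the second."""

    def __init__(self, g1: ReconciledGeneTree, g2: ReconciledGeneTree,
                 adjacencies: ExtantAdjacencySet):
        self.g1 = g1
        self.g2 = g2
        self.adjacencies = adjacencies
        leaves1 = {n.label: n for n in g1.extant_leaves()}
        leaves2 = {n.label: n for n in g2.extant_leaves()}
        self.adjacent_pairs: set[tuple[str, str]] = set()
        for a, b in adjacencies:
            if a in leaves1 and b in leaves2:
                l1, l2 = leaves1[a], leaves2[b]
            elif b in leaves1 and a in leaves2:
                l1, l2 = leaves1[b], leaves2[a]
            else:
                raise ModelError(
                    f"adjacency ({a}, {b}) does not link a leaf of the first "
                    "tree to a leaf of the second"
                )
            if l1.species is not l2.species:
                raise ModelError(
                    f"adjacency ({a}, {b}) spans species "
                    f"{l1.species.label} and {l2.species.label}"
                )
            self.adjacent_pairs.add((l1.label, l2.label))
        if not self.adjacent_pairs:
            raise ModelError("instance has no extant adjacency linking the two trees")

    def is_adjacent(self, g1: GeneNode, g2: GeneNode) -> bool:
        return (g1.label, g2.label) in self.adjacent_pairs


# ---------------------------------------------------------------------------
# Adjacency forests
# ---------------------------------------------------------------------------

class AdjacencyNode:
    """A node of an adjacency tree: a pair of gene nodes with an adjacency
    event; ``is_root_gain`` marks roots created by a scored AGain event."""

    __slots__ = ("g1", "g2", "event", "children", "is_root_gain")

    def __init__(self, g1: GeneNode, g2: GeneNode, event: str,
                 children: list["AdjacencyNode"] | None = None,
                 is_root_gain: bool = False):
        self.g1 = g1
        self.g2 = g2
        self.event = event
        self.children: list[AdjacencyNode] = children or []
        self.is_root_gain = is_root_gain

    @property
    def species(self) -> SpeciesNode:
        return self.g1.species

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"AdjacencyNode({self.g1.label}|{self.g2.label}|{self.event})"


class AdjacencyForest:
    """A forest of adjacency trees over one instance."""

    def __init__(self, roots: list[AdjacencyNode]):
        self.roots = list(roots)
        self._canonicalize()

    def _canonicalize(self) -> None:
        def sort_children(node: AdjacencyNode) -> None:
            node.children.sort(key=lambda c: (c.g1.index, c.g2.index))
            for c in node.children:
                sort_children(c)
        for r in self.roots:
            sort_children(r)
        self.roots.sort(key=lambda r: (r.g1.index, r.g2.index))

    def iter_nodes(self):
        stack = list(self.roots)
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def n_gains(self) -> int:
        return sum(1 for r in self.roots if r.is_root_gain)

    def n_breaks(self) -> int:
        return sum(1 for n in self.iter_nodes() if n.event == ABREAK)

    def serialize(self) -> str:
        """Canonical, injective serialization (children in gene-preorder)."""
        def ser(node: AdjacencyNode) -> str:
            head = f"{node.g1.label}|{node.g2.label}|{node.event}"
            if node.is_leaf:
                return head
            return "(" + ",".join(ser(c) for c in node.children) + ")" + head
        parts = [("+" if r.is_root_gain else "") + ser(r) for r in self.roots]
        return ";".join(parts)

    def __repr__(self):
        return f"AdjacencyForest<{len(self.roots)} trees>"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _validate_forest_structure(forest: AdjacencyForest) -> None:
    for node in forest.iter_nodes():
        if node.g1.species is not node.g2.species:
            raise ModelError(
                f"adjacency node {node!r} pairs genes of different species"
            )
        if node.is_leaf and node.event not in ADJ_LEAF_EVENTS:
            raise ModelError(f"adjacency leaf {node!r} has internal event")
        if not node.is_leaf and node.event not in ADJ_INTERNAL_EVENTS:
            raise ModelError(f"internal adjacency node {node!r} has leaf event")


def score_forest(forest: AdjacencyForest, costs: CostParams = CostParams()) -> float:
    """Parsimony score: AG * (#gains) + AB * (#breaks).

    Adjacency presence at the instance root pair is free (gains are charged
    only on absent-to-present transitions), so only roots flagged as gains
    count.  With unit penalties this is the plain event count s_a(F).
    """
    _validate_forest_structure(forest)
    return costs.ag * forest.n_gains() + costs.ab * forest.n_breaks()


def boltzmann_factor(forest: AdjacencyForest, costs: CostParams = CostParams(),
                     params: EnsembleParams = EnsembleParams()) -> float:
    """exp(-s_a(F)/kT), the unnormalized Boltzmann weight of a forest."""
    return math.exp(-score_forest(forest, costs) / params.kT)


def validate_forest_against_instance(forest: AdjacencyForest,
                                     instance: DecoInstance) -> list[str]:
    """Structural check of a forest against the event model, independent of
    any DP recurrence.

    Verifies that ADup nodes pair two co-specific GDup genes, Spec adjacency
    nodes pair two Spec genes, GDup adjacency nodes involve at least one GDup
    gene, and that the extant leaves of the forest are exactly the observed
    extant adjacencies, each appearing once.
    """
    problems: list[str] = []
    seen_extant: list[tuple[str, str]] = []
    for node in forest.iter_nodes():
        tag = f"{node.g1.label}|{node.g2.label}"
        if node.g1.species is not node.g2.species:
            problems.append(f"{tag}: genes from different species")
        e1, e2 = node.g1.event, node.g2.event
        if node.event == ADUP:
            if not (e1 == GDUP and e2 == GDUP):
                problems.append(f"{tag}: ADup at a ({e1},{e2}) gene pair")
            if len(node.children) != 2:
                problems.append(f"{tag}: ADup node must have two children")
        elif node.event == SPEC:
            if not (e1 == SPEC and e2 == SPEC):
                problems.append(f"{tag}: Spec adjacency at a ({e1},{e2}) gene pair")
            if len(node.children) != 2:
                problems.append(f"{tag}: Spec adjacency node must have two children")
        elif node.event == GDUP:
            if GDUP not in (e1, e2):
                problems.append(f"{tag}: GDup adjacency with no duplicated gene")
            if len(node.children) != 1:
                problems.append(f"{tag}: GDup adjacency node must have one child")
        elif node.event == EXTANT:
            if not (e1 == EXTANT and e2 == EXTANT):
                problems.append(f"{tag}: Extant adjacency at a ({e1},{e2}) gene pair")
            if not instance.is_adjacent(node.g1, node.g2):
                problems.append(f"{tag}: extant leaf is not an observed adjacency")
            seen_extant.append((node.g1.label, node.g2.label))
        elif node.event == GLOSS:
            if GLOSS not in (e1, e2):
                problems.append(f"{tag}: GLoss adjacency leaf with no lost gene")
        elif node.event == ALOSS:
            if not (e1 == GLOSS and e2 == GLOSS):
                problems.append(f"{tag}: ALoss leaf at a ({e1},{e2}) gene pair")
        elif node.event == ABREAK:
            if node.children:
                problems.append(f"{tag}: ABreak must be a leaf")
        else:
            problems.append(f"{tag}: unknown event {node.event!r}")
    if len(seen_extant) != len(set(seen_extant)):
        problems.append("an extant adjacency appears more than once")
    missing = instance.adjacent_pairs - set(seen_extant)
    for a, b in sorted(missing):
        problems.append(f"observed extant adjacency {a}|{b} missing from forest")
    return problems
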