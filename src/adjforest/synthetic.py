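"""Exhaustive enumeration of the adjacency-forest space on small instances
(the brute-force oracle) and a forward simulator of synthetic instances.

The oracle materializes, by direct recursive set construction (union /
Cartesian product in place of min / +), every adjacency forest the DP scheme
generates, with its score.  It is deliberately a separate implementation
path from :mod:`adjforest.dp`: it never consults transition records or DP
tables, so agreement between the two (minimum score, partition function,
sampling frequencies, adjacency probabilities, and the exact equality of the
counting-semiring value with the number of pairwise-distinct forests) is a
meaningful correctness certificate.

The simulator evolves two gene families and one adjacency forward along a
random species tree, with per-branch duplication and loss probabilities and
per-transmission adjacency gain and break probabilities, and returns the
reconciled trees, the surviving extant adjacencies and the true ancestral
adjacencies — the ground truth used in recovery experiments.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass

import numpy as np

from .model import (
    ABREAK, ADUP, ALOSS, EXTANT, GDUP, GLOSS, SPEC,
    AdjacencyForest, AdjacencyNode, CostParams, DecoInstance,
    ExtantAdjacencySet, GeneNode, ModelError, ReconciledGeneTree,
    SpeciesNode, SpeciesTree,
)


class ForestSpaceOverflow(RuntimeError):
    """The forest space exceeds the enumeration budget."""


# immutable forest fragments: node = (g1, g2, event, children-tuple)
def _leaf(g1, g2, event):
    return (g1, g2, event, ())


class ForestSpace:
    """The complete solution space F(G1,G2) of one instance."""

    def __init__(self, forests: list[tuple[AdjacencyForest, float]]):
        self.forests = forests
        serials = [f.serialize() for f, _ in forests]
        if len(set(serials)) != len(serials):
            raise ModelError("enumerated forests are not pairwise distinct")

    def __len__(self):
        return len(self.forests)

    def __iter__(self):
        return iter(self.forests)

    def min_score(self) -> float:
        return min(s for _, s in self.forests)


def enumerate_forests(instance: DecoInstance,
                      costs: CostParams = CostParams(),
                      max_count: int = 10 ** 6) -> ForestSpace:
    """Materialize every adjacency forest of the instance with its score."""
    memo: dict[tuple[int, int, int], list] = {}
    adj = instance.is_adjacent

    def combine(parts, node_builder, gains_inc, breaks_inc, gained_states=()):
        """Cartesian product of per-call fragment lists."""
        out = []
        for combo in itertools.product(*parts):
            roots = ()
            for frag in combo:
                roots = roots + frag[1]
            for i in gained_states:
                roots = roots + (combo[i][0],)
            node = node_builder(combo)
            gains = gains_inc + sum(f[2] for f in combo)
            breaks = breaks_inc + sum(f[3] for f in combo)
            out.append((node, roots, gains, breaks))
            if len(out) > max_count:
                raise ForestSpaceOverflow(
                    f"forest space exceeds {max_count} at one pair")
        return out

    def frags(state: int, g1: GeneNode, g2: GeneNode) -> list:
        key = (state, g1.index, g2.index)
        if key in memo:
            return memo[key]
        e1, e2 = g1.event, g2.event
        out: list = []
        if e1 == GLOSS or e2 == GLOSS:
            if state == 1:
                event = ALOSS if (e1 == GLOSS and e2 == GLOSS) else GLOSS
                out = [(_leaf(g1, g2, event), (), 0, 0)]
            else:
                out = [(None, (), 0, 0)]
        elif e1 == EXTANT and e2 == EXTANT:
            if adj(g1, g2):
                out = [(_leaf(g1, g2, EXTANT), (), 0, 0)] if state == 1 else []
            else:
                out = [] if state == 1 else [(None, (), 0, 0)]
        elif e1 == SPEC and e2 == SPEC:
            a1, b1 = g1.children
            a2, b2 = g2.children
            if a1.species is not a2.species:
                a2, b2 = b2, a2
            pa, pb = (a1, a2), (b1, b2)
            for sa, sb in ((1, 1), (1, 0), (0, 1), (0, 0)):
                parts = [frags(sa, *pa), frags(sb, *pb)]
                if state == 1:
                    def spec_node(combo, sa=sa, sb=sb):
                        ca = combo[0][0] if sa else _leaf(*pa, ABREAK)
                        cb = combo[1][0] if sb else _leaf(*pb, ABREAK)
                        return (g1, g2, SPEC, (ca, cb))
                    out += combine(parts, spec_node, 0, (1 - sa) + (1 - sb))
                else:
                    gained = tuple(i for i, s in enumerate((sa, sb)) if s == 1)
                    out += combine(parts, lambda combo: None, sa + sb, 0,
                                   gained_states=gained)
                if len(out) > max_count:
                    raise ForestSpaceOverflow(
                        f"forest space exceeds {max_count} at one pair")
        else:
            if e1 == GDUP and e2 == GDUP and state == 1:
                a1, b1 = g1.children
                a2, b2 = g2.children
                for p_on, p_off in (
                        (((a1, a2), (b1, b2)), ((a1, b2), (b1, a2))),
                        (((a1, b2), (b1, a2)), ((a1, a2), (b1, b2)))):
                    parts = [frags(1, *p_on[0]), frags(1, *p_on[1]),
                             frags(0, *p_off[0]), frags(0, *p_off[1])]
                    def adup_node(combo):
                        return (g1, g2, ADUP, (combo[0][0], combo[1][0]))
                    out += combine(parts, adup_node, 0, 0)
            if e1 == GDUP:
                a, b = g1.children
                pa, pb = (a, g2), (b, g2)
            elif e2 == GDUP:
                a, b = g2.children
                pa, pb = (g1, a), (g1, b)
            else:  # pragma: no cover - exhaustive
                raise ModelError(f"unhandled event pair ({e1},{e2})")
            if state == 1:
                out += combine([frags(1, *pa), frags(1, *pb)],
                               lambda c: (g1, g2, GDUP, (c[0][0],)),
                               1, 0, gained_states=(1,))
                out += combine([frags(1, *pa), frags(0, *pb)],
                               lambda c: (g1, g2, GDUP, (c[0][0],)), 0, 0)
                out += combine([frags(0, *pa), frags(1, *pb)],
                               lambda c: (g1, g2, GDUP, (c[1][0],)), 0, 0)
                out += combine([frags(0, *pa), frags(0, *pb)],
                               lambda c: (g1, g2, GDUP,
                                          (_leaf(g1, g2, ABREAK),)), 0, 1)
            else:
                for sa, sb in ((0, 0), (1, 0), (0, 1), (1, 1)):
                    gained = tuple(i for i, s in enumerate((sa, sb)) if s == 1)
                    out += combine([frags(sa, *pa), frags(sb, *pb)],
                                   lambda combo: None, sa + sb, 0,
                                   gained_states=gained)
            if len(out) > max_count:
                raise ForestSpaceOverflow(
                    f"forest space exceeds {max_count} at one pair")
        memo[key] = out
        return out

    def to_adj(node, is_root_gain=False) -> AdjacencyNode:
        g1, g2, event, children = node
        return AdjacencyNode(g1, g2, event, [to_adj(c) for c in children],
                             is_root_gain=is_root_gain)

    r1, r2 = instance.g1.root, instance.g2.root
    forests: list[tuple[AdjacencyForest, float]] = []
    for state in (1, 0):
        for node, roots, gains, breaks in frags(state, r1, r2):
            trees = []
            if node is not None:
                trees.append(to_adj(node))
            trees.extend(to_adj(r, is_root_gain=True) for r in roots)
            forest = AdjacencyForest(trees)
            forests.append((forest, gains * costs.ag + breaks * costs.ab))
            if len(forests) > max_count:
                raise ForestSpaceOverflow(
                    f"forest space exceeds {max_count} forests")
    return ForestSpace(forests)


def forest_present_pairs(forest: AdjacencyForest) -> set[tuple[str, str]]:
    """Gene pairs at which the forest asserts adjacency presence (every node
    except bare break markers)."""
    return {(n.g1.label, n.g2.label) for n in forest.iter_nodes()
            if n.event != ABREAK}


def oracle_probabilities(space: ForestSpace, kT: float
                         ) -> tuple[float, dict[tuple[str, str], float]]:
    """Partition function and exact per-pair adjacency probabilities by
    direct summation over the enumerated space.

    The probability map is computed with a max-shift (probabilities are
    ratios, so the shift cancels) and is therefore stable at any kT; the
    returned Z is the plain unshifted sum.
    """
    if not len(space):
        raise ModelError("empty forest space")
    scores = [s for _, s in space]
    smin = min(scores)
    z_plain = sum(math.exp(-s / kT) for s in scores)
    shifted = [math.exp(-(s - smin) / kT) for s in scores]
    z_shifted = sum(shifted)
    probs: dict[tuple[str, str], float] = {}
    for (forest, _), w in zip(space, shifted):
        for pair in forest_present_pairs(forest):
            probs[pair] = probs.get(pair, 0.0) + w
    return z_plain, {pair: w / z_shifted for pair, w in probs.items()}


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Conditions of a forward simulation.

    Rearrangement events are rare relative to gene-level events, so the
    default adjacency gain/break probabilities sit well below the per-branch
    duplication/loss probabilities.
    """
    n_species: int = 4
    dup_prob: float = 0.12
    loss_prob: float = 0.08
    gain_rate: float = 0.05
    break_rate: float = 0.05
    seed: int = 0
    max_extant_leaves: int = 8
    max_retries: int = 500

    def __post_init__(self):
        for p in (self.dup_prob, self.loss_prob, self.gain_rate, self.break_rate):
            if not 0.0 <= p <= 1.0:
                raise ModelError("simulation probabilities must lie in [0,1]")
        if self.n_species < 1:
            raise ModelError("need at least one species")


def _random_species_tree(rng, n_species: int) -> SpeciesTree:
    labels = list(string.ascii_uppercase[:n_species])
    nodes = [SpeciesNode(lab) for lab in labels]
    counter = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = SpeciesNode(f"N{counter}")
        counter += 1
        parent.children = [a, b]
        a.parent = parent
        b.parent = parent
        nodes.append(parent)
    return SpeciesTree(nodes[0])


def _evolve_gene_tree(rng, species: SpeciesTree, params: SimulationParams,
                      tree_tag: str) -> ReconciledGeneTree | None:
    counters: dict[str, int] = {}

    def fresh(prefix: str) -> str:
        counters[prefix] = counters.get(prefix, 0) + 1
        return f"{prefix}_{counters[prefix]}"

    def evolve(s: SpeciesNode) -> GeneNode:
        if rng.random() < params.dup_prob:
            return GeneNode(fresh(f"{s.label}_{tree_tag}_dup"), s, GDUP,
                            [evolve(s), evolve(s)])
        if rng.random() < params.loss_prob:
            return GeneNode(fresh(f"LOSS_{s.label}_{tree_tag}"), s, GLOSS)
        if s.is_leaf:
            return GeneNode(fresh(f"{s.label}_{tree_tag}"), s, EXTANT)
        return GeneNode(fresh(f"{s.label}_{tree_tag}_anc"), s, SPEC,
                        [evolve(c) for c in s.children])

    root = evolve(species.root)
    tree = ReconciledGeneTree(root, species)
    n_extant = len(tree.extant_leaves())
    if n_extant == 0 or n_extant > params.max_extant_leaves:
        return None
    return tree


def simulate_instance(params: SimulationParams
                      ) -> tuple[SpeciesTree, DecoInstance, set[tuple[str, str]]]:
    """Simulate a species tree, two reconciled gene trees, and the forward
    evolution of one adjacency; returns the instance (extant adjacencies)
    and the set of true ancestral (pre-speciation) adjacencies.

    The simulation retries internally until at least one extant adjacency
    survives; a fixed seed reproduces the instance exactly.
    """
    rng = np.random.default_rng(params.seed)
    for _ in range(params.max_retries):
        species = _random_species_tree(rng, params.n_species)
        t1 = _evolve_gene_tree(rng, species, params, "g1")
        t2 = _evolve_gene_tree(rng, species, params, "g2")
        if t1 is None or t2 is None:
            continue
        extant: set[tuple[str, str]] = set()
        truth: set[tuple[str, str]] = set()

        def walk(g1: GeneNode, g2: GeneNode, present: bool) -> None:
            e1, e2 = g1.event, g2.event
            if e1 == GLOSS or e2 == GLOSS:
                return
            if e1 == EXTANT and e2 == EXTANT:
                if present:
                    extant.add((g1.label, g2.label))
                return
            if present and e1 == SPEC and e2 == SPEC:
                truth.add((g1.label, g2.label))

            def child_state(parent_present: bool) -> bool:
                if parent_present:
                    return rng.random() >= params.break_rate
                return rng.random() < params.gain_rate

            if e1 == SPEC and e2 == SPEC:
                a1, b1 = g1.children
                a2, b2 = g2.children
                if a1.species is not a2.species:
                    a2, b2 = b2, a2
                walk(a1, a2, child_state(present))
                walk(b1, b2, child_state(present))
            elif e1 == GDUP and e2 == GDUP and present and rng.random() < 0.5:
                # simultaneous adjacency duplication along a random pairing
                a1, b1 = g1.children
                a2, b2 = g2.children
                if rng.random() < 0.5:
                    a2, b2 = b2, a2
                walk(a1, a2, child_state(True))
                walk(b1, b2, child_state(True))
                walk(a1, b2, False)
                walk(b1, a2, False)
            else:
                if e1 == GDUP:
                    copies = [(c, g2) for c in g1.children]
                else:
                    copies = [(g1, c) for c in g2.children]
                keeper = rng.integers(2) if present else -1
                for i, (x, y) in enumerate(copies):
                    walk(x, y, child_state(present) if i == keeper
                         else child_state(False))

        walk(t1.root, t2.root, True)
        if not extant:
            continue
        adjs = ExtantAdjacencySet()
        for a, b in sorted(extant):
            adjs.add(a, b)
        return species, DecoInstance(t1, t2, adjs), truth
    raise ModelError(
        "no extant adjacency survived after "
        f"{params.max_retries} simulation attempts")
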