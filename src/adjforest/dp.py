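"""The DeCo dynamic program over pairs of reconciled gene trees.

For every pair of gene nodes (g1, g2) with s(g1) = s(g2), two quantities are
computed: ``c1(g1,g2)`` (an adjacency is present between g1 and g2) and
``c0(g1,g2)`` (it is absent).  The recurrence is expressed once as a list of
transitions — each alternative of each left-hand side, with its constant
gain/break increments and its recursive calls — and then evaluated under a
pluggable algebra: (min,+) for parsimony, (sum,times) for the partition
function, or exact integer counting.  The same transition records drive the
deterministic backtrack, the stochastic (Boltzmann) backtrack and the
inside-outside inversion.

Recurrence cases
----------------
* Extant x Extant: c1 is feasible iff the pair is an observed extant
  adjacency, c0 iff it is not.
* one gene lost (GLoss): the adjacency history is truncated, both states cost
  nothing.  For rescaling-homogeneity the cell carries the alpha-exponent of
  its virtual expansion over the surviving subtree (see ``_loss_expansion``).
* Spec x Spec: the adjacency follows the speciation into both descendant
  species; in each it either persists or breaks (state 1) / stays absent or
  is gained (state 0).
* GDup x other (and symmetrically): the duplicated gene's two copies each
  keep or lack the adjacency; keeping both costs a gain, losing both a break.
* GDup x GDup: either a simultaneous adjacency duplication (ADup) along one
  of the two copy pairings — with the cross pairs explicitly absent — or the
  first tree's duplication is resolved first (cascade).  The cascade for
  state 0 is single-sided, which keeps the scheme unambiguous: every forest
  is generated by exactly one execution.

Root convention: adjacency presence at the root pair incurs no gain; the
score of the instance is min(c1(r1,r2), c0(r1,r2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import (
    ABREAK, ADUP, ALOSS, EXTANT, GDUP, GLOSS, SPEC,
    AdjacencyForest, AdjacencyNode, CostParams, DecoInstance, EnsembleParams,
    GeneNode, ModelError, ReconciledGeneTree, ExtantAdjacencySet,
)

INF = math.inf


def _exp(x: float) -> float:
    """exp() that saturates to +inf instead of raising OverflowError."""
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf

# assembly tags
T_EXTANT = "extant"          # state-1 extant adjacency leaf
T_EMPTY = "empty"            # state-0 leaf-ish case: nothing produced
T_LOSS = "loss"              # state-1 leaf truncated by gene loss (GLoss/ALoss)
T_SPEC = "spec"              # state-1 speciation node
T_ABSENT = "absent"          # state-0 internal: children may be gained roots
T_DUP_KEEP = "dup_keep"      # state-1 one-side duplication, one copy inherits
T_DUP_BOTH = "dup_both"      # state-1 one-side duplication, second copy gained
T_DUP_BREAK = "dup_break"    # state-1 broken at the duplication: ABreak leaf
T_ADUP = "adup"              # state-1 simultaneous adjacency duplication


@dataclass(frozen=True)
class Transition:
    """One alternative (RHS) of a left-hand side ``(state, pair)``.

    ``gains``/``breaks`` are the constant event increments of the
    alternative; ``calls`` are the recursive calls as (state, pair-id)
    tuples; ``alpha_sites`` counts the rescaling-factor occurrences charged
    to this alternative (call sites whose callee pair has both gene events
    != GDup, plus the loss-expansion exponent for truncated cells).
    """
    lhs: tuple[int, int]
    gains: int
    breaks: int
    calls: tuple[tuple[int, int], ...]
    alpha_sites: int
    tag: str

    def cost(self, costs: CostParams) -> float:
        return self.gains * costs.ag + self.breaks * costs.ab


class RescalingNeeded(ArithmeticError):
    """A partition-function cell left floating range; carries the offending
    pair and the direction of failure ('overflow' or 'underflow')."""

    def __init__(self, pair_id: int, direction: str, pair_label: str = ""):
        self.pair_id = pair_id
        self.direction = direction
        super().__init__(
            f"partition-function {direction} at pair {pair_label or pair_id}; "
            "rerun with a rescaling factor (alpha)"
        )


class PairScheme:
    """The transition system for one instance: valid pairs in double
    post-order plus every LHS alternative, independent of any algebra."""

    def __init__(self, instance: DecoInstance):
        self.instance = instance
        nodes1 = list(instance.g1.postorder())
        nodes2 = list(instance.g2.postorder())
        self.pairs: list[tuple[GeneNode, GeneNode]] = []
        self.pair_id: dict[tuple[int, int], int] = {}
        for n1 in nodes1:
            for n2 in nodes2:
                if n1.species is n2.species:
                    self.pair_id[(n1.index, n2.index)] = len(self.pairs)
                    self.pairs.append((n1, n2))
        self.root_pair = self.pair_id.get(
            (instance.g1.root.index, instance.g2.root.index))
        # transitions[state][pair] -> list of Transition (empty = infeasible)
        self.transitions: list[list[list[Transition]]] = [
            [[] for _ in self.pairs] for _ in (0, 1)]
        self.kappa: list[int] = [0] * len(self.pairs)
        self._nonGDup_count1 = self._count_non_gdup(instance.g1)
        self._nonGDup_count2 = self._count_non_gdup(instance.g2)
        for pid, (g1, g2) in enumerate(self.pairs):
            self._build_pair(pid, g1, g2)

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _count_non_gdup(tree: ReconciledGeneTree) -> dict[int, int]:
        """Per node, the number of nodes in its subtree (itself included)
        whose event is not GDup."""
        counts: dict[int, int] = {}
        for node in tree.postorder():
            counts[node.index] = (0 if node.event == GDUP else 1) + sum(
                counts[c.index] for c in node.children)
        return counts

    def pid(self, g1: GeneNode, g2: GeneNode) -> int:
        return self.pair_id[(g1.index, g2.index)]

    def _site(self, g1: GeneNode, g2: GeneNode) -> int:
        """1 iff a call to (g1,g2) carries a rescaling factor."""
        return int(g1.event != GDUP and g2.event != GDUP)

    def _loss_expansion(self, g1: GeneNode, g2: GeneNode) -> int:
        """Alpha exponent of a gene-loss-truncated cell.

        A call on a pair with one lost gene is virtually expanded over the
        surviving partner's subtree (one call per proper descendant, unless
        the partner is itself a leaf), so the number of rescaling factors per
        execution stays constant.  The exponent equals the number of proper
        descendants of the surviving node whose event is not GDup.
        """
        if g1.event == GLOSS and not g2.is_leaf:
            return self._nonGDup_count2[g2.index] - int(g2.event != GDUP)
        if g2.event == GLOSS and not g1.is_leaf:
            return self._nonGDup_count1[g1.index] - int(g1.event != GDUP)
        return 0

    def _add(self, state: int, pid: int, gains: int, breaks: int,
             calls: list[tuple[int, GeneNode, GeneNode]], tag: str,
             extra_alpha: int = 0) -> None:
        resolved = tuple((s, self.pid(x, y)) for s, x, y in calls)
        sites = sum(self._site(x, y) for _, x, y in calls) + extra_alpha
        self.transitions[state][pid].append(
            Transition((state, pid), gains, breaks, resolved, sites, tag))

    # -- case analysis ----------------------------------------------------

    def _build_pair(self, pid: int, g1: GeneNode, g2: GeneNode) -> None:
        e1, e2 = g1.event, g2.event
        if e1 == GLOSS or e2 == GLOSS:
            nu = self._loss_expansion(g1, g2)
            self._add(1, pid, 0, 0, [], T_LOSS, extra_alpha=nu)
            self._add(0, pid, 0, 0, [], T_EMPTY, extra_alpha=nu)
        elif e1 == EXTANT and e2 == EXTANT:
            if self.instance.is_adjacent(g1, g2):
                self._add(1, pid, 0, 0, [], T_EXTANT)
            else:
                self._add(0, pid, 0, 0, [], T_EMPTY)
        elif e1 == SPEC and e2 == SPEC:
            a1, b1 = g1.children
            a2, b2 = g2.children
            if a1.species is not a2.species:
                a2, b2 = b2, a2
            pa = (a1, a2)
            pb = (b1, b2)
            for sa, sb, gains, breaks in (
                    (1, 1, 0, 0), (1, 0, 0, 1), (0, 1, 0, 1), (0, 0, 0, 2)):
                self._add(1, pid, gains, breaks,
                          [(sa, *pa), (sb, *pb)], T_SPEC)
            for sa, sb in ((0, 0), (1, 0), (0, 1), (1, 1)):
                self._add(0, pid, sa + sb, 0,
                          [(sa, *pa), (sb, *pb)], T_ABSENT)
        elif e1 == GDUP and e2 == GDUP:
            a1, b1 = g1.children
            a2, b2 = g2.children
            # simultaneous adjacency duplication, two pairings; the cross
            # pairs are explicitly absent (may host later gains)
            self._add(1, pid, 0, 0,
                      [(1, a1, a2), (1, b1, b2), (0, a1, b2), (0, b1, a2)],
                      T_ADUP)
            self._add(1, pid, 0, 0,
                      [(1, a1, b2), (1, b1, a2), (0, a1, a2), (0, b1, b2)],
                      T_ADUP)
            self._cascade(pid, (a1, g2), (b1, g2))
        elif e1 == GDUP:
            a1, b1 = g1.children
            self._cascade(pid, (a1, g2), (b1, g2))
        elif e2 == GDUP:
            a2, b2 = g2.children
            self._cascade(pid, (g1, a2), (g1, b2))
        else:  # pragma: no cover - exhaustive over valid reconciliations
            raise ModelError(f"unhandled event pair ({e1},{e2})")

    def _cascade(self, pid: int, pa: tuple[GeneNode, GeneNode],
                 pb: tuple[GeneNode, GeneNode]) -> None:
        """One-side duplication: copies `pa`/`pb` of the duplicated gene
        paired with the partner."""
        self._add(1, pid, 1, 0, [(1, *pa), (1, *pb)], T_DUP_BOTH)
        self._add(1, pid, 0, 0, [(1, *pa), (0, *pb)], T_DUP_KEEP)
        self._add(1, pid, 0, 0, [(0, *pa), (1, *pb)], T_DUP_KEEP)
        self._add(1, pid, 0, 1, [(0, *pa), (0, *pb)], T_DUP_BREAK)
        for sa, sb in ((0, 0), (1, 0), (0, 1), (1, 1)):
            self._add(0, pid, sa + sb, 0, [(sa, *pa), (sb, *pb)], T_ABSENT)

    # -- rescaling bookkeeping --------------------------------------------

    def compute_kappa(self) -> list[int]:
        """Per-pair rescaling exponent; asserts homogeneity (every
        alternative of both states of a pair yields the same count)."""
        kappa = [0] * len(self.pairs)
        for pid in range(len(self.pairs)):
            counts = set()
            for state in (0, 1):
                for tr in self.transitions[state][pid]:
                    counts.add(tr.alpha_sites +
                               sum(kappa[q] for _, q in tr.calls))
            if not counts:
                continue
            if len(counts) != 1:
                g1, g2 = self.pairs[pid]
                raise ModelError(
                    "inhomogeneous rescaling count at pair "
                    f"{g1.label}|{g2.label}: {sorted(counts)}")
            kappa[pid] = counts.pop()
        self.kappa = kappa
        return kappa


class DPTables:
    """Filled c0/c1 tables for one instance under one algebra."""

    def __init__(self, scheme: PairScheme, algebra: str, costs: CostParams,
                 params: EnsembleParams | None):
        self.scheme = scheme
        self.algebra = algebra
        self.costs = costs
        self.params = params
        n = len(scheme.pairs)
        self.c: list[list] = [[None] * n, [None] * n]

    def value(self, state: int, pid: int):
        return self.c[state][pid]

    def root_values(self):
        rp = self.scheme.root_pair
        return self.c[1][rp], self.c[0][rp]


def compute_tables(instance: DecoInstance,
                   costs: CostParams = CostParams(),
                   algebra: str = "min-plus",
                   params: EnsembleParams | None = None,
                   scheme: PairScheme | None = None) -> DPTables:
    """Fill the DP tables in double post-order under the requested algebra.

    ``algebra`` is one of ``min-plus`` (parsimony costs), ``sum-times``
    (Boltzmann partition values, requires ``params``) or ``counting`` (exact
    integer solution counts, costs ignored).
    """
    if scheme is None:
        scheme = PairScheme(instance)
    if algebra == "sum-times":
        if params is None:
            raise ModelError("sum-times algebra requires ensemble parameters")
        scheme.compute_kappa()
    tables = DPTables(scheme, algebra, costs, params)
    n = len(scheme.pairs)
    for pid in range(n):
        for state in (0, 1):
            alts = scheme.transitions[state][pid]
            if algebra == "min-plus":
                best = INF
                for tr in alts:
                    v = tr.cost(costs)
                    for s, q in tr.calls:
                        v += tables.c[s][q]
                    if v < best:
                        best = v
                tables.c[state][pid] = best
            elif algebra == "counting":
                total = 0
                for tr in alts:
                    v = 1
                    for s, q in tr.calls:
                        v *= tables.c[s][q]
                    total += v
                tables.c[state][pid] = total
            elif algebra == "sum-times":
                kT = params.kT
                log_alpha = math.log(params.alpha)
                total = 0.0
                structurally_positive = False
                for tr in alts:
                    # single exponentiation so the rescaling factor can lift
                    # atomic Boltzmann factors that would underflow alone
                    w = _exp(-tr.cost(costs) / kT + tr.alpha_sites * log_alpha)
                    v = w
                    positive = w > 0.0
                    for s, q in tr.calls:
                        cv = tables.c[s][q]
                        v *= cv
                        positive = positive and cv > 0.0
                    if positive:
                        structurally_positive = True
                    total += v
                g1, g2 = scheme.pairs[pid]
                label = f"{g1.label}|{g2.label}"
                if math.isinf(total):
                    raise RescalingNeeded(pid, "overflow", label)
                if total == 0.0 and structurally_positive:
                    raise RescalingNeeded(pid, "underflow", label)
                tables.c[state][pid] = total
            else:
                raise ModelError(f"unknown algebra {algebra!r}")
    return tables


def parsimony_score(tables: DPTables) -> float:
    """min(c1(r1,r2), c0(r1,r2)) under the (min,+) algebra."""
    if tables.algebra != "min-plus":
        raise ModelError("parsimony_score requires min-plus tables")
    c1, c0 = tables.root_values()
    return min(c1, c0)


# ---------------------------------------------------------------------------
# Forest assembly (shared by deterministic and stochastic backtrack)
# ---------------------------------------------------------------------------

def assemble(scheme: PairScheme, state: int, pid: int, tr: Transition,
             sub: list[tuple[AdjacencyNode | None, list[AdjacencyNode]]]
             ) -> tuple[AdjacencyNode | None, list[AdjacencyNode]]:
    """Build (node, gained_roots) for one chosen alternative, given the
    already-assembled results of its recursive calls."""
    g1, g2 = scheme.pairs[pid]
    roots: list[AdjacencyNode] = []
    for _, extra in sub:
        roots.extend(extra)
    tag = tr.tag
    if tag == T_EXTANT:
        return AdjacencyNode(g1, g2, EXTANT), roots
    if tag == T_LOSS:
        event = ALOSS if (g1.event == GLOSS and g2.event == GLOSS) else GLOSS
        return AdjacencyNode(g1, g2, event), roots
    if tag == T_EMPTY:
        return None, roots
    if tag == T_SPEC:
        children = []
        for (s, q), (node, _) in zip(tr.calls, sub):
            if s == 1:
                children.append(node)
            else:
                qa, qb = scheme.pairs[q]
                children.append(AdjacencyNode(qa, qb, ABREAK))
        return AdjacencyNode(g1, g2, SPEC, children), roots
    if tag == T_ABSENT:
        for (s, _), (node, _) in zip(tr.calls, sub):
            if s == 1:
                node.is_root_gain = True
                roots.append(node)
        return None, roots
    if tag == T_DUP_KEEP:
        kept = next(node for (s, _), (node, _) in zip(tr.calls, sub) if s == 1)
        return AdjacencyNode(g1, g2, GDUP, [kept]), roots
    if tag == T_DUP_BOTH:
        (na, _), (nb, _) = sub
        nb.is_root_gain = True
        roots.append(nb)
        return AdjacencyNode(g1, g2, GDUP, [na]), roots
    if tag == T_DUP_BREAK:
        # the adjacency survives into the duplication event and is lost
        # there: a GDup node witnessing the duplication, with a break leaf
        # (distinct from a break charged before the pair by a Spec parent)
        broken = AdjacencyNode(g1, g2, ABREAK)
        return AdjacencyNode(g1, g2, GDUP, [broken]), roots
    if tag == T_ADUP:
        children = [node for (s, _), (node, _) in zip(tr.calls, sub) if s == 1]
        return AdjacencyNode(g1, g2, ADUP, children), roots
    raise ModelError(f"unknown assembly tag {tag!r}")  # pragma: no cover


def backtrack_optimal(tables: DPTables, instance: DecoInstance) -> AdjacencyForest:
    """One parsimonious forest; ties broken deterministically (first
    alternative in transcription order; c1 preferred over c0 at the root)."""
    if tables.algebra != "min-plus":
        raise ModelError("backtrack_optimal requires min-plus tables")
    scheme = tables.scheme
    eps = 1e-9

    def walk(state: int, pid: int):
        target = tables.c[state][pid]
        for tr in scheme.transitions[state][pid]:
            v = tr.cost(tables.costs)
            for s, q in tr.calls:
                v += tables.c[s][q]
            if v <= target + eps:
                sub = [walk(s, q) for s, q in tr.calls]
                return assemble(scheme, state, pid, tr, sub)
        raise ModelError("inconsistent min-plus tables")  # pragma: no cover

    c1, c0 = tables.root_values()
    state = 1 if c1 <= c0 else 0
    node, roots = walk(state, scheme.root_pair)
    forest = [node] + roots if node is not None else roots
    return AdjacencyForest(forest)


# ---------------------------------------------------------------------------
# Instance construction
# ---------------------------------------------------------------------------

def build_instances(trees: list[ReconciledGeneTree],
                    adjacencies: ExtantAdjacencySet) -> list[DecoInstance]:
    """Group extant adjacencies into instances: one instance per unordered
    pair of trees sharing at least one adjacency.  A tree adjacent to itself
    yields a self-instance against a second working copy."""
    leaf_tree: dict[str, int] = {}
    for i, t in enumerate(trees):
        for leaf in t.extant_leaves():
            leaf_tree[leaf.label] = i
    groups: dict[tuple[int, int], ExtantAdjacencySet] = {}
    for a, b in adjacencies:
        if a not in leaf_tree or b not in leaf_tree:
            raise ModelError(f"adjacency ({a}, {b}) matches no gene tree leaf")
        key = tuple(sorted((leaf_tree[a], leaf_tree[b])))
        groups.setdefault(key, ExtantAdjacencySet()).add(a, b)
    instances = []
    for (i, j), adjs in sorted(groups.items()):
        g1 = trees[i]
        g2 = trees[j] if j != i else trees[i].copy()
        instances.append(DecoInstance(g1, g2, adjs))
    return instances
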