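"""LCA reconciliation of plain gene trees against a species tree.

The most-parsimonious (LCA) reconciliation maps every gene-tree node g to
the lowest common ancestor of its leaves' species; an internal node is a
duplication (GDup) iff it maps to the same species as one of its children,
otherwise a speciation (Spec).  Loss leaves are then inserted so that every
Spec node's children map exactly to the two species children and every
duplication child starts in its parent's species — i.e. the output satisfies
every reconciled-tree invariant with losses materialized as leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    EXTANT, GDUP, GLOSS, SPEC,
    GeneNode, ModelError, ReconciledGeneTree, SpeciesNode, SpeciesTree,
    validate_gene_tree,
)


@dataclass
class PlainNode:
    """An unannotated gene-tree node (topology and labels only)."""
    label: str | None
    children: list["PlainNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def lca_reconcile(root: PlainNode, species: SpeciesTree,
                  leaf_map: dict[str, str]) -> ReconciledGeneTree:
    """Reconcile a plain binary gene tree; ``leaf_map`` sends every gene
    leaf label to an extant species label."""
    counters = {"anc": 0, "loss": 0}

    def fresh(kind: str, hint: str) -> str:
        counters[kind] += 1
        return f"{hint}_{kind}{counters[kind]}"

    def min_leaf_label(node: PlainNode) -> str:
        if node.is_leaf:
            return node.label or ""
        return min(min_leaf_label(c) for c in node.children)

    def species_of(node: PlainNode) -> SpeciesNode:
        if node.is_leaf:
            if node.label is None or node.label not in leaf_map:
                raise ModelError(f"gene leaf {node.label!r} has no species mapping")
            s = species[leaf_map[node.label]]
            if not s.is_leaf:
                raise ModelError(
                    f"leaf {node.label!r} maps to non-extant species {s.label!r}")
            return s
        kids = [species_of(c) for c in node.children]
        s = kids[0]
        for k in kids[1:]:
            s = species.lca(s, k)
        return s

    def loss_chain(sub: GeneNode, top: SpeciesNode) -> GeneNode:
        """Wrap ``sub`` (at species s(sub)) in Spec nodes from ``top`` down,
        adding a loss leaf in each bypassed sister species."""
        target = sub.species
        if top is target:
            return sub
        path: list[SpeciesNode] = []
        cur = target
        while cur is not top:
            cur = cur.parent
            if cur is None:
                raise ModelError("species path construction failed")
            path.append(cur)
        node = sub
        for t in path:  # bottom-up from just above target to top
            on_path = t.children[0] if species.is_descendant_or_equal(
                target, t.children[0]) else t.children[1]
            sister = t.children[1] if on_path is t.children[0] else t.children[0]
            loss = GeneNode(fresh("loss", f"LOSS_{sister.label}"), sister, GLOSS)
            node = GeneNode(fresh("anc", t.label), t, SPEC, [node, loss])
        return node

    def build(node: PlainNode) -> GeneNode:
        s = species_of(node)
        if node.is_leaf:
            return GeneNode(node.label, s, EXTANT)
        kids = sorted(node.children, key=min_leaf_label)
        sub = [build(c) for c in kids]
        event = GDUP if any(c.species is s for c in sub) else SPEC
        if event == GDUP:
            completed = [loss_chain(c, s) for c in sub]
        else:
            completed = []
            for c in sub:
                side = s.children[0] if species.is_descendant_or_equal(
                    c.species, s.children[0]) else s.children[1]
                completed.append(loss_chain(c, side))
        label = node.label or fresh("anc", s.label)
        return GeneNode(label, s, event, completed)

    if root.is_leaf:
        return ReconciledGeneTree(build(root), species)
    if any(len(n.children) not in (0, 2) for n in _iter_plain(root)):
        raise ModelError("gene tree must be binary for LCA reconciliation")
    return ReconciledGeneTree(build(root), species)


def _iter_plain(root: PlainNode):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def validate_reconciliation(tree: ReconciledGeneTree,
                            species: SpeciesTree) -> list[str]:
    """Re-check every reconciled-tree invariant; empty list iff valid."""
    return validate_gene_tree(tree, species)


def count_losses(tree: ReconciledGeneTree) -> int:
    return sum(1 for n in tree.nodes if n.event == GLOSS)
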