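"""Readers and writers: Newick species trees, NHX-annotated reconciled gene
trees, two-column adjacency lists, adjacency forests, probability matrices
and summary tables.

Reconciliation annotations use the NHX dialect (tags ``S=<species>`` and
``Ev=<Spec|GDup|GLoss|Extant>`` on every node); untagged gene trees are
accepted together with a leaf->species map and are LCA-reconciled.  All text
outputs are TSV, UTF-8, LF line endings, with deterministic (sorted) row
order.
"""

from __future__ import annotations

import io as _io

import dendropy

from .model import (
    EXTANT, GDUP, GLOSS, SPEC,
    AdjacencyForest, AdjacencyNode, DecoInstance, ExtantAdjacencySet,
    GeneNode, ModelError, ReconciledGeneTree, SpeciesNode, SpeciesTree,
)
from .reconcile import PlainNode, lca_reconcile
from .boltzmann import AdjacencyProbabilityMatrix


class FormatError(ModelError):
    """Malformed input text."""


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def _dendropy_tree(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=False,
                                 extract_comment_metadata=False)
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from None


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or None


def parse_species_tree(text: str) -> SpeciesTree:
    """Parse a rooted binary species tree; every node must be labelled."""
    dtree = _dendropy_tree(text)

    def convert(dnode: dendropy.Node) -> SpeciesNode:
        label = _node_label(dnode)
        if not label:
            raise FormatError("species tree node without a label")
        node = SpeciesNode(label)
        for child in dnode.child_nodes():
            sub = convert(child)
            sub.parent = node
            node.children.append(sub)
        return node

    try:
        return SpeciesTree(convert(dtree.seed_node))
    except FormatError:
        raise
    except ModelError as exc:
        raise FormatError(str(exc)) from None


# ---------------------------------------------------------------------------
# Reconciled gene trees
# ---------------------------------------------------------------------------

def _nhx_tags(dnode: dendropy.Node, extra: list[str] | None = None
              ) -> dict[str, str]:
    tags: dict[str, str] = {}
    comments = list(dnode.comments)
    if dnode.taxon is not None:
        comments.extend(dnode.taxon.comments)
    comments.extend(extra or [])
    for comment in comments:
        body = comment.strip()
        if body.startswith("&&NHX"):
            for part in body.split(":")[1:]:
                if "=" in part:
                    key, value = part.split("=", 1)
                    tags[key] = value
    return tags


def parse_leaf_species_map(text: str) -> dict[str, str]:
    """Two-column gene-label / species-label mapping."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected two columns")
        mapping[fields[0]] = fields[1]
    return mapping


def parse_reconciled_gene_trees(text: str, species: SpeciesTree,
                                leaf_map: dict[str, str] | None = None
                                ) -> list[ReconciledGeneTree]:
    """One Newick tree per non-empty line; either NHX-annotated on every
    node, or plain topology plus a leaf->species map (LCA-reconciled)."""
    trees = []
    counter = [0]
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        dtree = _dendropy_tree(line)
        tagged = any(_nhx_tags(n) for n in dtree.preorder_node_iter())
        # a degenerate single-node tree carries its comment at tree level
        tagged = tagged or bool(_nhx_tags(dtree.seed_node, dtree.comments))
        try:
            if tagged:
                trees.append(_convert_nhx(dtree, species, counter))
            else:
                if leaf_map is None:
                    raise FormatError(
                        "gene tree has no NHX annotations and no "
                        "leaf->species map was supplied")
                trees.append(lca_reconcile(
                    _convert_plain(dtree), species, leaf_map))
        except ModelError as exc:
            raise type(exc)(f"gene tree on line {lineno}: {exc}") from None
    if not trees:
        raise FormatError("no gene trees found")
    return trees


def _convert_nhx(dtree: dendropy.Tree, species: SpeciesTree,
                 counter: list[int]) -> ReconciledGeneTree:
    def convert(dnode: dendropy.Node) -> GeneNode:
        extra = dtree.comments if dnode is dtree.seed_node else None
        tags = _nhx_tags(dnode, extra)
        if "S" not in tags or "Ev" not in tags:
            raise FormatError(
                f"node {_node_label(dnode)!r} lacks NHX S=/Ev= annotations")
        if tags["S"] not in species:
            raise FormatError(f"unknown species label {tags['S']!r}")
        if tags["Ev"] not in (SPEC, GDUP, GLOSS, EXTANT):
            raise FormatError(f"unknown event {tags['Ev']!r}")
        label = _node_label(dnode)
        if not label:
            counter[0] += 1
            label = f"node{counter[0]}"
        children = [convert(c) for c in dnode.child_nodes()]
        return GeneNode(label, species[tags["S"]], tags["Ev"], children)

    return ReconciledGeneTree(convert(dtree.seed_node), species)


def _convert_plain(dtree: dendropy.Tree) -> PlainNode:
    def convert(dnode: dendropy.Node) -> PlainNode:
        return PlainNode(_node_label(dnode),
                         [convert(c) for c in dnode.child_nodes()])
    return convert(dtree.seed_node)


def write_reconciled_gene_tree(tree: ReconciledGeneTree) -> str:
    """NHX serialization (inverse of the tagged parser)."""
    def ser(node: GeneNode) -> str:
        tag = f"[&&NHX:S={node.species.label}:Ev={node.event}]"
        if node.is_leaf:
            return f"{node.label}{tag}"
        inner = ",".join(ser(c) for c in node.children)
        return f"({inner}){node.label}{tag}"
    return ser(tree.root) + ";"


# ---------------------------------------------------------------------------
# Adjacencies
# ---------------------------------------------------------------------------

def parse_adjacencies(text: str, trees: list[ReconciledGeneTree]
                      ) -> ExtantAdjacencySet:
    """Two gene labels per non-empty line ('#' comments skipped); every
    label must name an extant leaf and both genes must share a species."""
    leaves: dict[str, GeneNode] = {}
    for tree in trees:
        for leaf in tree.extant_leaves():
            leaves[leaf.label] = leaf
    adjacencies = ExtantAdjacencySet()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected two gene labels")
        a, b = fields
        for lab in (a, b):
            if lab not in leaves:
                raise FormatError(
                    f"line {lineno}: unknown extant gene {lab!r}")
        if a == b:
            raise FormatError(f"line {lineno}: self-adjacency {a!r}")
        if leaves[a].species is not leaves[b].species:
            raise FormatError(
                f"line {lineno}: genes {a!r} and {b!r} belong to species "
                f"{leaves[a].species.label} and {leaves[b].species.label}")
        adjacencies.add(a, b)
    return adjacencies


def write_adjacencies(adjacencies: ExtantAdjacencySet) -> str:
    return "".join(f"{a}\t{b}\n" for a, b in adjacencies)


# ---------------------------------------------------------------------------
# Adjacency forests
# ---------------------------------------------------------------------------

def write_forest(forest: AdjacencyForest) -> str:
    """Header line with the event counts, then one Newick-like line per
    adjacency tree with node labels ``g1|g2|event`` (root label suffixed
    ``|gain`` for scored gains)."""
    def ser(node: AdjacencyNode) -> str:
        head = f"{node.g1.label}|{node.g2.label}|{node.event}"
        if node.is_leaf:
            return head
        return "(" + ",".join(ser(c) for c in node.children) + ")" + head
    gains, breaks = forest.n_gains(), forest.n_breaks()
    lines = [f"#score\t{gains + breaks}\tgains\t{gains}\tbreaks\t{breaks}"]
    for root in forest.roots:
        lines.append(ser(root) + ("|gain" if root.is_root_gain else "") + ";")
    return "\n".join(lines) + "\n"


def parse_forest(text: str, instance: DecoInstance) -> AdjacencyForest:
    """Inverse of :func:`write_forest` (gene labels resolved against the
    instance's trees)."""
    genes1 = {n.label: n for n in instance.g1.nodes}
    genes2 = {n.label: n for n in instance.g2.nodes}
    roots = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not line.endswith(";"):
            raise FormatError(f"forest tree line must end with ';': {line!r}")
        node, pos = _parse_forest_node(line[:-1], 0, genes1, genes2)
        if pos != len(line) - 1:
            raise FormatError(f"trailing characters in forest line: {line!r}")
        roots.append(node)
    return AdjacencyForest(roots)


def _parse_forest_node(s: str, pos: int, genes1, genes2):
    children = []
    if pos < len(s) and s[pos] == "(":
        pos += 1
        while True:
            child, pos = _parse_forest_node(s, pos, genes1, genes2)
            children.append(child)
            if pos >= len(s):
                raise FormatError("unbalanced parentheses in forest line")
            if s[pos] == ",":
                pos += 1
                continue
            if s[pos] == ")":
                pos += 1
                break
    end = pos
    while end < len(s) and s[end] not in "(),":
        end += 1
    parts = s[pos:end].split("|")
    if len(parts) not in (3, 4):
        raise FormatError(f"bad forest node label {s[pos:end]!r}")
    l1, l2, event = parts[:3]
    gain = len(parts) == 4 and parts[3] == "gain"
    if l1 not in genes1 or l2 not in genes2:
        raise FormatError(f"unknown gene pair {l1!r}|{l2!r} in forest")
    node = AdjacencyNode(genes1[l1], genes2[l2], event, children,
                         is_root_gain=gain)
    return node, end


# ---------------------------------------------------------------------------
# Probability matrices and summaries
# ---------------------------------------------------------------------------

def write_probability_matrix(matrix: AdjacencyProbabilityMatrix) -> str:
    """TSV gene1/gene2/species/probability, 10 significant digits,
    lexicographic row order."""
    lines = ["gene1\tgene2\tspecies\tprobability"]
    for (l1, l2), entry in sorted(matrix.items()):
        p = entry["probability"]
        if not 0.0 <= p <= 1.0:
            raise FormatError(f"probability {p} for {l1}|{l2} outside [0,1]")
        lines.append(f"{l1}\t{l2}\t{entry['species']}\t{p:.10g}")
    return "\n".join(lines) + "\n"


def read_probability_matrix(text: str) -> AdjacencyProbabilityMatrix:
    entries: dict[tuple[str, str], dict] = {}
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != ["gene1", "gene2", "species",
                                             "probability"]:
        raise FormatError("missing probability-matrix header")
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"line {lineno}: expected 4 columns")
        l1, l2, sp, p = fields
        p = float(p)
        if not 0.0 <= p <= 1.0:
            raise FormatError(f"line {lineno}: probability {p} outside [0,1]")
        entries[(l1, l2)] = {"probability": p, "species": sp}
    return AdjacencyProbabilityMatrix(entries)


def write_summary(summary) -> str:
    """TSV rendering of an ensemble summary table (pandas DataFrame with
    (metric, kT) column MultiIndex)."""
    buf = _io.StringIO()
    summary.to_csv(buf, sep="\t")
    return buf.getvalue()
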