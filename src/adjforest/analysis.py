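"""Threshold filtering of ancestral adjacencies by Boltzmann probability,
syntenic-conflict accounting and summary tables.

An ancestral adjacency candidate is a pair of pre-speciation genes — both
internal speciation (Spec) nodes of their trees, i.e. not duplicated within
their own species.  A gene can be adjacent to at most two neighbours along a
(linear or circular) chromosome, so a gene incident to three or more
retained adjacencies is in syntenic conflict; raising the probability
threshold should shed low-support adjacencies and with them conflicts.
"""

from __future__ import annotations

import pandas as pd

from .model import EXTANT, SPEC, AdjacencyForest, GeneNode, ModelError
from .boltzmann import AdjacencyProbabilityMatrix
from .synthetic import forest_present_pairs


def is_ancestral_candidate(g1: GeneNode, g2: GeneNode) -> bool:
    """True iff both genes are pre-speciation genes that were not duplicated
    within their species (event Spec on both)."""
    return g1.event == SPEC and g2.event == SPEC


def _entry_is_candidate(entry: dict) -> bool:
    if "candidate" in entry:
        return bool(entry["candidate"])
    return is_ancestral_candidate(entry["g1"], entry["g2"])


def filter_by_probability(matrix: AdjacencyProbabilityMatrix,
                          threshold: float) -> set[tuple[str, str]]:
    """Ancestral-candidate pairs with probability >= threshold (the
    threshold-1 row tolerates 1e-9 of numerical slack)."""
    if not 0.0 <= threshold <= 1.0:
        raise ModelError(f"threshold {threshold} outside [0,1]")
    cut = 1.0 - 1e-9 if threshold >= 1.0 else threshold
    return {pair for pair, entry in matrix.items()
            if _entry_is_candidate(entry) and entry["probability"] >= cut}


def count_conflicts(retained: set[tuple[str, str]]) -> tuple[int, int]:
    """(number of genes incident to >=1 retained adjacency, number of genes
    incident to >=3 of them — the syntenic conflicts)."""
    degree: dict[str, int] = {}
    for a, b in retained:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    return len(degree), sum(1 for d in degree.values() if d >= 3)


def summarize(matrices: dict[float, list[AdjacencyProbabilityMatrix]],
              thresholds: list[float]) -> pd.DataFrame:
    """Grid of retained-adjacency / gene / conflict counts: one row per
    probability threshold, one column group per kT."""
    if list(thresholds) != sorted(thresholds):
        raise ModelError("thresholds must be sorted ascending")
    kTs = list(matrices)
    columns = pd.MultiIndex.from_tuples(
        [(metric, kT) for metric in ("genes", "adjacencies", "conflicts")
         for kT in kTs], names=["metric", "kT"])
    rows = []
    for threshold in thresholds:
        row = {}
        for kT in kTs:
            genes = set()
            n_adj = 0
            conflicts = 0
            for i, matrix in enumerate(matrices[kT]):
                retained = filter_by_probability(matrix, threshold)
                n_adj += len(retained)
                g, c = count_conflicts(retained)
                # gene identity is per matrix: independently generated
                # instances may reuse labels
                genes.update((i, lab) for pair in retained for lab in pair)
                conflicts += c
            row[("genes", kT)] = len(genes)
            row[("adjacencies", kT)] = n_adj
            row[("conflicts", kT)] = conflicts
        rows.append(row)
    frame = pd.DataFrame(rows, index=pd.Index(thresholds, name="threshold"),
                         columns=columns)
    return frame


def _forest_tree_roots(forest: AdjacencyForest) -> tuple[int, int]:
    node = forest.roots[0]
    g1, g2 = node.g1, node.g2
    while g1.parent is not None:
        g1 = g1.parent
    while g2.parent is not None:
        g2 = g2.parent
    return id(g1), id(g2)


def sample_frequency_matrix(samples: list[AdjacencyForest]
                            ) -> AdjacencyProbabilityMatrix:
    """Per-pair fraction of sampled forests containing the adjacency — the
    sampling estimator of the exact Boltzmann probabilities."""
    if not samples:
        raise ModelError("need at least one sampled forest")
    origins = {_forest_tree_roots(f) for f in samples if f.roots}
    if len(origins) > 1:
        raise ModelError("samples stem from different instances")
    counts: dict[tuple[str, str], dict] = {}
    for forest in samples:
        seen = set()
        for node in forest.iter_nodes():
            if node.event == "ABreak":
                continue
            pair = (node.g1.label, node.g2.label)
            if pair in seen:
                continue
            seen.add(pair)
            entry = counts.setdefault(pair, {
                "hits": 0,
                "species": node.species.label,
                "g1": node.g1,
                "g2": node.g2,
                "candidate": is_ancestral_candidate(node.g1, node.g2),
                "ancestral": node.g1.event != EXTANT or node.g2.event != EXTANT,
            })
            entry["hits"] += 1
    n = len(samples)
    entries = {}
    for pair, entry in counts.items():
        entries[pair] = {**{k: v for k, v in entry.items() if k != "hits"},
                         "probability": entry["hits"] / n}
    return AdjacencyProbabilityMatrix(entries)
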