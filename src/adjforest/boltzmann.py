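"""Boltzmann-ensemble algorithms: partition function, homogeneous rescaling,
stochastic backtracking and the inside-outside algorithm.

Changing the DP algebra from (min,+) to (sum,times) — every atomic cost C
becoming a factor exp(-C/kT) — turns the parsimony recursion into the
partition function Z(G1,G2) = sum over all adjacency forests of
exp(-s_a(F)/kT).  Because the scheme is unambiguous, a stochastic backtrack
that branches on each alternative t_i with probability t_i / (LHS value)
draws forests exactly under the Boltzmann distribution P(F) =
exp(-s_a(F)/kT)/Z.

Partition values grow (or vanish) exponentially with tree size, so a
homogeneous rescaling factor alpha is attached to every recursive call whose
callee pair has both gene events != GDup; the number of such factors per
complete execution (kappa) depends only on the instance, never on the
sampled forest, so rescaled sampling is bias-free and Z = Z_alpha /
alpha^kappa.

The inside-outside inversion propagates, from the root down, the total
weight d_x(g1,g2) of all truncated contexts of a DP state; the exact
Boltzmann probability of an ancestral adjacency is then
c1(g1,g2) * d1(g1,g2) / Z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    EXTANT, SPEC, AdjacencyForest, CostParams, DecoInstance, EnsembleParams,
    ModelError,
)
from .dp import (
    DPTables, PairScheme, RescalingNeeded, Transition, _exp, assemble,
    compute_tables,
)


@dataclass
class PartitionResult:
    """Partition function of one instance.

    ``Z_alpha`` is the value the rescaled DP actually computed (sum of
    c1 and c0 at the root pair); ``Z`` the de-rescaled partition function
    Z_alpha / alpha^kappa_root, also held as ``log_Z`` which stays finite
    when Z itself leaves floating range.
    """
    Z_alpha: float
    kappa_root: int
    kT: float
    alpha: float
    tables: DPTables

    @property
    def log_Z(self) -> float:
        return math.log(self.Z_alpha) - self.kappa_root * math.log(self.alpha)

    @property
    def Z(self) -> float:
        return math.exp(self.log_Z)


def _scheme_for(instance, scheme=None) -> PairScheme:
    return scheme if scheme is not None else PairScheme(instance)


def partition_function(instance: DecoInstance,
                       costs: CostParams = CostParams(),
                       params: EnsembleParams = EnsembleParams(),
                       scheme: PairScheme | None = None) -> PartitionResult:
    """Z(G1,G2) = c1(r1,r2) + c0(r1,r2) under the (sum,times) algebra.

    Raises :class:`RescalingNeeded` when a table cell over- or underflows;
    :func:`choose_rescaling` can then pick a suitable alpha.
    """
    scheme = _scheme_for(instance, scheme)
    tables = compute_tables(instance, costs, "sum-times", params, scheme)
    c1, c0 = tables.root_values()
    if c1 + c0 <= 0.0:
        g1, g2 = scheme.pairs[scheme.root_pair]
        raise RescalingNeeded(scheme.root_pair, "underflow",
                              f"{g1.label}|{g2.label} (root)")
    kappa_root = scheme.kappa[scheme.root_pair]
    return PartitionResult(c1 + c0, kappa_root, params.kT, params.alpha, tables)


def choose_rescaling(instance: DecoInstance,
                     costs: CostParams = CostParams(),
                     params: EnsembleParams = EnsembleParams(),
                     scheme: PairScheme | None = None,
                     max_attempts: int = 16) -> float:
    """Pick a rescaling factor alpha that keeps all table cells finite.

    Returns 1.0 when the plain computation already succeeds.  Otherwise the
    magnitude of Z is estimated from a min-plus pilot (the partition function
    is dominated by exp(-s*/kT) with s* the parsimony score) and alpha is set
    to exp(-log Z_est / kappa_root), the value that drives the rescaled root
    value towards 1; the guess is refined by bisection on log(alpha) if cells
    still leave floating range.
    """
    scheme = _scheme_for(instance, scheme)

    def attempt(alpha: float) -> float:
        """Full inside + outside pass; returns log(Z_alpha) on success."""
        tables = compute_tables(instance, costs, "sum-times",
                                EnsembleParams(kT=params.kT, alpha=alpha),
                                scheme)
        c1, c0 = tables.root_values()
        if c1 + c0 <= 0.0:
            raise RescalingNeeded(scheme.root_pair, "underflow", "(root)")
        outside_tables(tables)
        return math.log(c1 + c0)

    try:
        attempt(1.0)
        return 1.0
    except RescalingNeeded:
        pass
    kappa_root = scheme.kappa[scheme.root_pair]
    if kappa_root <= 0:
        raise ModelError("instance admits no homogeneous rescaling (kappa=0)")
    pilot = compute_tables(instance, costs, "min-plus", None, scheme)
    s_star = min(pilot.root_values())
    log_alpha = s_star / (params.kT * kappa_root)
    lo, hi = -math.inf, math.inf
    best: float | None = None
    for _ in range(max_attempts):
        log_alpha = max(-700.0, min(700.0, log_alpha))
        alpha = math.exp(log_alpha)
        try:
            log_z_alpha = attempt(alpha)
        except RescalingNeeded as exc:
            if exc.direction == "underflow":
                lo = log_alpha
                log_alpha = log_alpha * 2 + 1 if math.isinf(hi) else (lo + hi) / 2
            else:
                hi = log_alpha
                log_alpha = log_alpha * 2 - 1 if math.isinf(lo) else (lo + hi) / 2
            continue
        best = alpha
        # drive the rescaled root value towards 1 so the outside pass has
        # the same headroom as the inside pass
        if abs(log_z_alpha) <= 50.0:
            return alpha
        log_alpha -= log_z_alpha / kappa_root
    if best is not None:
        return best
    raise ModelError("failed to find a workable rescaling factor")


# ---------------------------------------------------------------------------
# Stochastic backtrack
# ---------------------------------------------------------------------------

def sample_forests(instance: DecoInstance,
                   costs: CostParams = CostParams(),
                   params: EnsembleParams = EnsembleParams(),
                   n: int = 1,
                   seed: int | None = None,
                   tables: DPTables | None = None) -> list[AdjacencyForest]:
    """Draw ``n`` independent adjacency forests under the Boltzmann
    distribution by stochastic backtracking.

    At every LHS, an alternative is selected with probability proportional
    to its contribution to the cell value (cumulative-sum inversion in
    recorded order); identical seeds give identical samples, and the
    homogeneous rescaling leaves the distribution unchanged.
    """
    if not isinstance(seed, (int, np.integer, type(None))):
        raise ModelError("seed must be an integer or None")
    if n < 0:
        raise ModelError("sample count must be nonnegative")
    if tables is None:
        result = partition_function(instance, costs, params)
        tables = result.tables
    scheme = tables.scheme
    rng = np.random.default_rng(seed)
    kT = params.kT
    log_alpha = math.log(params.alpha)

    def weight(tr: Transition) -> float:
        w = _exp(-tr.cost(costs) / kT + tr.alpha_sites * log_alpha)
        for s, q in tr.calls:
            w *= tables.c[s][q]
        return w

    def draw(state: int, pid: int):
        alts = scheme.transitions[state][pid]
        total = tables.c[state][pid]
        u = rng.random() * total
        acc = 0.0
        chosen = None
        last_positive = None
        for tr in alts:
            w = weight(tr)
            if w <= 0.0:
                continue
            last_positive = tr
            acc += w
            if u <= acc:
                chosen = tr
                break
        if chosen is None:  # numerical slack: fall back to last feasible
            chosen = last_positive
        if chosen is None:
            raise ModelError("stochastic backtrack entered an infeasible cell")
        sub = [draw(s, q) for s, q in chosen.calls]
        return assemble(scheme, state, pid, chosen, sub)

    c1, c0 = tables.root_values()
    forests = []
    for _ in range(n):
        state = 1 if rng.random() * (c1 + c0) <= c1 else 0
        node, roots = draw(state, scheme.root_pair)
        forests.append(AdjacencyForest(([node] if node is not None else []) + roots))
    return forests


# ---------------------------------------------------------------------------
# Inside-outside
# ---------------------------------------------------------------------------

class OutsideTables:
    """Outside values d_x(g1,g2): total (rescaled) Boltzmann weight of all
    DP-scheme executions truncated at the state (x, g1, g2)."""

    def __init__(self, scheme: PairScheme, d: list[list[float]]):
        self.scheme = scheme
        self.d = d

    def value(self, state: int, pid: int) -> float:
        return self.d[state][pid]


def outside_tables(tables: DPTables) -> OutsideTables:
    """Invert the DP scheme: starting from d=1 at the root pair, every
    transition l -> r propagates d(l) * exp(-C_r/kT) * (product of the other
    calls' inside values) onto each of its recursive calls, in reverse double
    post-order."""
    if tables.algebra != "sum-times":
        raise ModelError("outside_tables requires sum-times tables")
    scheme = tables.scheme
    kT = tables.params.kT
    log_alpha = math.log(tables.params.alpha)
    n = len(scheme.pairs)
    d = [[0.0] * n, [0.0] * n]
    rp = scheme.root_pair
    d[0][rp] = 1.0
    d[1][rp] = 1.0
    for pid in range(n - 1, -1, -1):
        for state in (0, 1):
            dl = d[state][pid]
            if dl == 0.0:
                continue
            if math.isinf(dl) or math.isnan(dl):
                g1, g2 = scheme.pairs[pid]
                raise RescalingNeeded(pid, "overflow",
                                      f"{g1.label}|{g2.label} (outside)")
            for tr in scheme.transitions[state][pid]:
                w = _exp(-tr.cost(tables.costs) / kT
                         + tr.alpha_sites * log_alpha)
                vals = [tables.c[s][q] for s, q in tr.calls]
                for i, (s, q) in enumerate(tr.calls):
                    contrib = dl * w
                    for j, v in enumerate(vals):
                        if j != i:
                            contrib *= v
                    d[s][q] += contrib
    return OutsideTables(scheme, d)


def transition_probabilities(tables: DPTables, outside: OutsideTables,
                             ) -> dict[Transition, float]:
    """Exact Boltzmann probability of every LHS -> RHS transition:
    P(l->r) = d(l) * exp(-C_r/kT) * prod(inside values of r) / Z."""
    scheme = tables.scheme
    kT = tables.params.kT
    log_alpha = math.log(tables.params.alpha)
    c1, c0 = tables.root_values()
    z_alpha = c1 + c0
    probs: dict[Transition, float] = {}
    for pid in range(len(scheme.pairs)):
        for state in (0, 1):
            dl = outside.d[state][pid]
            for tr in scheme.transitions[state][pid]:
                w = _exp(-tr.cost(tables.costs) / kT
                         + tr.alpha_sites * log_alpha)
                for s, q in tr.calls:
                    w *= tables.c[s][q]
                probs[tr] = dl * w / z_alpha
    return probs


class AdjacencyProbabilityMatrix:
    """Exact Boltzmann probability, per valid gene pair, that the ensemble
    contains an adjacency between the two genes."""

    def __init__(self, entries: dict[tuple[str, str], dict]):
        self.entries = entries

    def probability(self, label1: str, label2: str) -> float:
        return self.entries[(label1, label2)]["probability"]

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()


def adjacency_probability_matrix(instance: DecoInstance,
                                 costs: CostParams = CostParams(),
                                 params: EnsembleParams = EnsembleParams(),
                                 scheme: PairScheme | None = None,
                                 ) -> AdjacencyProbabilityMatrix:
    """P(adjacency between g1 and g2) = c1(g1,g2) * d1(g1,g2) / Z for every
    valid pair (observed extant adjacencies come out at exactly 1)."""
    scheme = _scheme_for(instance, scheme)
    result = partition_function(instance, costs, params, scheme)
    tables = result.tables
    outside = outside_tables(tables)
    z_alpha = result.Z_alpha
    entries: dict[tuple[str, str], dict] = {}
    for pid, (g1, g2) in enumerate(scheme.pairs):
        p = tables.c[1][pid] * outside.d[1][pid] / z_alpha
        if p < -1e-9 or p > 1 + 1e-9:
            raise ModelError(
                f"adjacency probability {p} out of range at {g1.label}|{g2.label}")
        p = min(1.0, max(0.0, p))
        entries[(g1.label, g2.label)] = {
            "probability": p,
            "species": g1.species.label,
            "ancestral": g1.event != EXTANT or g2.event != EXTANT,
            "candidate": g1.event == SPEC and g2.event == SPEC,
            "g1": g1,
            "g2": g2,
        }
    return AdjacencyProbabilityMatrix(entries)
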