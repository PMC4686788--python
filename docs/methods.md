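# Methods

## Model

A species tree *S* is rooted and binary; leaves are extant genomes.  A
reconciled gene tree maps every node *g* to a species *s(g)* and an event
*e(g)*: internal nodes are speciations (Spec — children map to the two
species children) or duplications (GDup — children stay in *s(g)*); leaves
are extant genes or losses (GLoss), with losses materialized as leaves so
every Spec node has a child on both sides.  Unordered pairs of extant genes
of one species are adjacencies; gene orientation, circular-chromosome end
effects and lateral transfer are not modelled.

The evolution of one adjacency along a pair of reconciled trees is an
adjacency forest: nodes are co-specific gene-node pairs carrying events
Spec, GDup, ADup (internal) or Extant, GLoss, ALoss, ABreak (leaves), and
adjacency gains are attached to tree roots.  The parsimony score charges
only gains (AG, default 1) and breaks (AB, default 1); all other events are
by-products of the gene trees.

## The recurrence

For every pair (g1, g2) with s(g1) = s(g2), two quantities c1/c0 (adjacency
present/absent below the pair) are defined by a case analysis on
(e(g1), e(g2)):

* **Extant × Extant** — c1 feasible iff the pair is an observed adjacency,
  c0 iff it is not.
* **one GLoss** — history truncated; both states cost nothing.
* **Spec × Spec** — children matched by species; under presence each side
  persists or breaks (AB per break); under absence each side stays absent
  or is gained (AG per gain).
* **GDup × other** (and symmetric) — the two copies of the duplicated gene
  against the partner: one copy inherits; both copies adjacent costs one
  gain; neither costs one break.
* **GDup × GDup** — either a simultaneous adjacency duplication along one of
  the two copy pairings, with the two cross pairs explicitly absent, or the
  first tree's duplication is resolved first (the same four alternatives as
  the one-sided case).  Under absence only the first-tree cascade is used.

Three transcription choices keep the scheme *unambiguous* (every forest is
generated by exactly one execution) and are certified on every test run by
exact integer equality between the counting-semiring value and the number
of pairwise-distinct enumerated forests:

1. the absent-state GDup × GDup case descends one fixed side (two-sided
   descent would generate, e.g., the all-absent forest twice);
2. the ADup alternatives carry explicit absent calls on the two cross
   pairs — also required for the rescaling count to be homogeneous;
3. a presence that ends at a duplication ("neither copy keeps it") is
   represented as a GDup node with an ABreak child at the same pair,
   structurally distinct from the bare ABreak marker a Spec parent places
   when the adjacency is not transmitted into a descendant species.  Both
   scenarios cost one break but are different histories (in the former the
   adjacency witnesses the duplication).

**Root convention.** Presence at the root pair costs no gain; the instance
score is min(c1, c0) at the root with no extra term.  Gains are charged
only on absent-to-present transitions, and the enumeration oracle, the
sampler and the forest scorer all share this convention.

## Ensemble algorithms

The scheme is evaluated under a pluggable algebra: (min, +) for parsimony,
(Σ, ×) with atomic factors exp(−C/kT) for the partition function, and plain
integer counting.  The same transition records drive a deterministic
backtrack (first alternative in transcription order; c1 preferred at the
root on ties), the stochastic backtrack (alternative t_i chosen with
probability t_i divided by the cell value, by cumulative-sum inversion over
one seeded NumPy generator per call), and the inside-outside inversion:
outside values d_x(g1,g2) start at 1 for both root states and accumulate
down the reverse evaluation order; the probability of an adjacency is
c1·d1/Z, of a transition d(l)·e^{−C_r/kT}·Π(inside values)/Z, and per-LHS
transition probabilities conserve the reach probability to 1e−12.

**Pseudo-temperature.**  kT defaults to 0.1.  kT → 0 concentrates on
co-optimal forests, kT → ∞ tends to the uniform distribution; 0.01 is
effectively the co-optimal limit in double precision.

## Rescaling

Partition values shrink/grow exponentially with tree size.  A factor α is
applied at every recursive call whose callee pair has both events ≠ GDup;
calls truncated by a gene loss are virtually expanded over the surviving
subtree (one factor per non-GDup proper descendant) so that the total count
κ per execution depends only on the pair, never on the sampled forest —
this homogeneity is asserted for every pair at table-build time.  Hence
Z_α = Z·α^κ, sampling is unbiased under any α, and probabilities are
α-invariant (verified to 1e−9).  α and the atomic Boltzmann factor are
combined in a single exponentiation (exp(−C/kT + sites·ln α)) so the factor
can lift weights that would underflow alone.

`choose_rescaling` returns 1 when the plain run succeeds; otherwise it
estimates log Z ≈ −s*/kT from a (min,+) pilot, starts at
α = exp(s*/(kT·κ_root)), refines towards Z_α ≈ 1 (so the outside pass has
the same headroom as the inside pass) and falls back to bisection on ln α.

Limits of the approach, stated plainly: rescaling shifts the absolute
magnitude of whole cells but never the relative weights within one, so
(a) sub-dominant alternatives more than ~300 orders of magnitude below the
dominant one are truncated — they are below double-precision epsilon of the
sum, so every reported number is still correct to machine precision; and
(b) when the score-to-κ distribution across the instance spans more than
the ~1400 log-units double precision offers (large instances with large
scores at kT ≤ 0.01), no single α works and `choose_rescaling` raises an
honest error rather than returning biased numbers.  Low-temperature
analyses of such instances should use the co-optimal limit directly.

## Synthetic data and the oracle

`simulate_instance` draws a random binary species tree, evolves two gene
families top-down with per-branch duplication (default 0.12) and loss
(default 0.08) probabilities, caps extant leaves at 8 by resampling, and
evolves one adjacency forward along the pair with per-transmission break
and gain probabilities (default 0.05 each — rearrangements are rare
relative to gene-level events).  It returns the reconciled trees (always
re-validated), the surviving extant adjacencies and the true ancestral
(pre-speciation) adjacencies.  What it does **not** emulate: genome-scale
linkage.  Every instance is generated independently and a gene belongs to
exactly one instance, so syntenic conflicts — which in real data accumulate
across the several instances a gene participates in — are essentially
absent at this scale; the threshold-filtering summaries therefore
demonstrate monotone filtering, not realistic conflict counts.  Passing
tests show the algorithms are exact on the model; they do not show
robustness to gene-tree errors, orientation effects or transfer, which the
model excludes.

The enumeration oracle materializes the full forest space of an instance by
direct recursive set construction under (∪, ×) semantics — a separate
implementation path that never touches DP tables or transition records —
with a 10⁶-forest budget.  DP/oracle agreement is checked for the minimum
score (exact), Z (1e−9 relative, kT ∈ {0.01 … 10}), the forest count
(exact integers), sampling (chi-square), and adjacency probabilities
(1e−9).

## Numerical and procedural choices

* Infeasible states are +∞ under (min,+) and exact 0 under (Σ,×).
* Probabilities are clamped to [0,1] only within 1e−9; larger excursions
  raise.
* Ties in the deterministic backtrack break on transcription order, making
  outputs byte-reproducible; all text outputs are sorted TSV.
* Ancestral-adjacency candidates are pairs with e(g) = Spec on both sides
  (pre-speciation, not duplicated within the species); the probability-1
  filter row tolerates 1e−9 slack.  Conflict counts use the gene reading:
  genes incident to ≥3 retained adjacencies.
* A tree adjacent to itself is analysed against a second working copy, the
  adjacency attached in one (lexicographic) orientation.
* The sampling goodness-of-fit gate runs twelve chi-square tests at the 1%
  level with 10,000 samples each; because an exact sampler still trips one
  of twelve 1%-level tests about 11% of the time, a failing instance is
  retested once on an independent replicate (family-wise false-alarm rate
  ~1e−4; a genuinely biased sampler fails both).
* Ground-truth recovery is assessed at kT = 0.01 with zero gain, break and
  loss rates (duplications kept): with losses a true ancestral adjacency
  can lose all extant evidence on both sides, making its presence formally
  unidentifiable (posterior 0.5 at any temperature), so the ≥0.99 recovery
  property is meaningful only in the loss-free regime.
* Problem sizes: correctness batteries use 200 enumerable instances with
  ≤8 extant leaves per tree; the rescaling-invariance study uses one
  noiseless instance with ~40–50 extant leaves per tree (κ ≈ 216), where
  α ∈ {0.1, 1, 10} all stay within floating range; the filtering summary
  uses 50 instances at kT ∈ {0.5, 0.1, 0.01}.

## Known limitations

Beyond the rescaling range limits and the single-instance conflict scale
discussed above: the package offers only LCA (most-parsimonious)
reconciliation for untagged trees; non-binary species trees, dated
reconciliations, lateral transfer (and the corresponding adjacency
machinery) and maximum-expected-accuracy forest construction are out of
scope.
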