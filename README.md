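# adjforest

Ancestral gene-adjacency reconstruction from pairs of reconciled gene trees,
under both parsimony and the Boltzmann ensemble.

## The problem

Two genes that sit next to each other on a chromosome form a *gene
adjacency*.  Given a species tree *S*, two reconciled gene trees *G1*, *G2*
(each node carrying a species *s(g)* and an event *e(g)* ∈ {Spec, GDup,
GLoss, Extant}) and the adjacencies observed between their extant genes, the
DeCo dynamic program reconstructs how the adjacency evolved: it persists
through speciations, duplicates when both genes duplicate together (ADup),
disappears with gene losses (GLoss/ALoss), breaks through rearrangement
(ABreak), and is created by rearrangement (AGain).  A full history is an
*adjacency forest* *F* with parsimony score

```
s_a(F) = AG · #gains + AB · #breaks        (default AG = AB = 1)
```

computed per pair of co-specific gene nodes via two quantities c1(g1,g2) /
c0(g1,g2) (adjacency present / absent), with the optimum
min(c1(r1,r2), c0(r1,r2)) at the root pair.

A single optimal forest is an arbitrary pick from a potentially huge set of
co-optimal and slightly sub-optimal scenarios.  This package treats the whole
solution space as a Boltzmann ensemble: each forest gets probability

```
P(F) = exp(−s_a(F)/kT) / Z,    Z = Σ_F exp(−s_a(F)/kT)
```

where the pseudo-temperature *kT* interpolates between the uniform
distribution over co-optimal forests (kT → 0) and over the whole space
(kT → ∞).  Replacing (min, +) by (Σ, ×) in the same unambiguous DP scheme
computes *Z*; a stochastic backtrack draws exact Boltzmann samples; and an
inside–outside pass yields, for every candidate ancestral adjacency, its
exact probability c1(g1,g2)·d1(g1,g2)/Z in O(n1·n2).  Low-probability
ancestral adjacencies can then be filtered out, which reduces *syntenic
conflicts* (genes with three or more inferred neighbours — impossible on a
chromosome).  Against numerical over/underflow the DP applies a homogeneous
rescaling factor α whose per-solution multiplicity κ depends only on the
instance, so Z = Z_α/α^κ and no probability is biased.

Intended users: comparative genomicists reconstructing ancestral gene
orders from reconciled gene trees, and anyone studying ensemble approaches
to dynamic programming on phylogenies.

## Worked example

Species tree `(A,B)C;`, a duplicated family `G1` against a family `G2` that
duplicated independently in both descendant species, and four conserved
extant adjacencies (`A1–A3`, `B1–B3`, `A2–A4`, `B2–B4`):

```bash
adjforest score --species species.nwk --gene-trees genes.nhx \
                --adjacencies adj.txt --out-dir out
# instance 0: n1=4 n2=4 score=1
cat out/instance0.forest.txt
# #gains  1  breaks  0
# (((A1|A3|Extant)A1|vA|GDup,(B1|B3|Extant)B1|vB|GDup)u1|r2|Spec)r1|r2|GDup;
# ((A2|A4|Extant)A2|vA|GDup,(B2|B4|Extant)B2|vB|GDup)u2|r2|Spec|gain;
```

The parsimonious history costs one event: the ancestral adjacency follows
the duplication of the `G1` root (node `r1|r2|GDup`), one copy (`u1`)
inherits it, and a single adjacency gain (the second tree, marked `|gain`)
creates the `u2`-side adjacency.  Two adjacency trees, one gain, no breaks.

```bash
adjforest probs --species species.nwk --gene-trees genes.nhx \
                --adjacencies adj.txt --kt 0.5 --out-dir out
# instance 0: n1=4 n2=4 log Z=-1.06764 alpha=1 kappa=10
grep -E "^(r1|u1|u2)" out/instance0.probabilities.tsv
# r1  r2  C  0.8672987021
# u1  r2  C  0.7314108074
# u2  r2  C  0.7314108074
```

At kT = 0.5 the ensemble puts probability 0.867 on the root-pair adjacency
and 0.731 on each candidate ancestral adjacency (`u1–r2`, `u2–r2`); extant
adjacencies always come out at 1.  Lowering `--kt` drives these towards the
parsimony solution; `adjforest sample` draws forests from the same
distribution, `adjforest summarize` tabulates retained
adjacencies/genes/conflicts over a probability-threshold grid, `adjforest
simulate` writes a synthetic dataset, and `adjforest enumerate` lists the
entire forest space of a small instance.

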