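# Methods

## Model overview and assumptions

The measure assumes that functional similarity between genes is encoded
jointly in two resources: the GO DAG with its annotations (specific shared
terms imply shared function) and a weighted gene co-functional network
(edge weight reflects evidence of shared function). Annotation-only
measures ignore the network; measures using only direct network edges
ignore indirect association. Here the network enters through the
stationary distribution of a random walk with restart (RWR), which
summarises *global* connectivity: two genes are relevant to each other if
a restarting walker started at one spends probability mass at the other,
whether or not they are adjacent.

The ontology side keeps only `is_a` and `part_of` edges within one
namespace; the DAG must be single-rooted and acyclic (both validated at
parse time). Annotations follow the true-path rule: a gene annotated to a
term implicitly annotates every ancestor, implemented as a bottom-up union
in one topological pass. Propagation crosses `part_of` edges the same way
as `is_a` — they are the only two kept, and part-of parents inherit their
parts' genes; this is the standard reading but it is a modelling choice,
not a forced one.

## The similarity pipeline

1. **RWR.** M′ is column-stochastic (each column of the weight matrix
   divided by its sum), which guarantees (I − cM′) is invertible for
   continuation c ∈ (0,1) and makes each stationary vector a probability
   distribution. Both a dense closed-form solve and a power iteration are
   provided; they agree to ≤ 1e−8 on all test graphs and the iteration's
   stopping rule (L1 change < tol) bounds its distance to the fixed point
   by tol/(1−c). R is symmetrised as (R+Rᵀ)/2 before the distance
   d = 1 − R is taken, because the walk on a weighted graph is asymmetric
   while the gene-set distance needs a metric-like symmetric d. Stationary
   probabilities are used as-is (no rescaling of R); only the term-level
   distances are normalised.

2. **Gene-set and term distance.** The set distance D uses
   sum-of-products of pairwise distances; any shared gene zeroes a product
   (self-distance 0), which makes D(G,G) = 0 and keeps the denominator
   2|G₁∪G₂| − Σ − Σ strictly positive for nonempty sets. Products over
   many factors are evaluated in log space with an explicit zero
   short-circuit. Raw distances are min–max normalised over all term
   pairs computed in a run (the full eligible-term matrix here); the
   bounds are stored in the context so later queries are reproducible. A
   degenerate span (all raw distances equal) maps everything to 0 —
   the network is treated as uninformative and the measure collapses
   toward annotation-only similarity. Terms with empty propagated gene
   sets stay in the DAG but are excluded from similarity (they would put
   log 0 into the score).

3. **Term similarity.** The path-constrained annotation set U replaces
   the full descendant closure of a common ancestor: only genes annotated
   to the compared terms, or directly to terms on a directed path from
   either term up to the ancestor, count. A term x lies on such a path iff
   it is an ancestor-or-self of t and a descendant-or-self of p, which the
   implementation uses instead of path enumeration; the test suite checks
   it against an explicit all-paths oracle. All logs are natural; the
   left factor of the score is a ratio of log differences and therefore
   base-invariant (unit-tested). |G_p|/|G| is read as the ratio of set
   sizes. When both terms annotate the whole genome the score's
   denominator vanishes; similarity is then defined as 0 since such terms
   carry no information. With several lowest common ancestors the maximum
   score is taken.

4. **Selection and aggregation.** Backgrounds use the population standard
   deviation over all other eligible terms (a seeded uniform sample,
   default cap 2000, for large ontologies). The significance threshold is
   the constant 1.6 (not 1.645), configurable. Tie-breaks: equal-size
   nonempty high/low sets prefer the high set; when neither set is
   populated the single best-|z| candidate is selected, so every term can
   form a significant pair; a degenerate background (σ = 0) falls back to
   the best-similarity candidate, keeping the aggregate total. Gene
   similarity averages best matches over the *direct* annotation sets —
   propagated closures would drown specific terms in shared ancestors.

5. **LFC benchmark.** The smoothing constant (default 0.001) prevents
   log 0 at similarity 1 while distorting distances by at most 0.1%. The
   "without g" convention applies to both the group-size factor and the
   intra-group sum. The per-EC average runs over the partner ECs that are
   actually gene-disjoint (the summation's own index set); weighting
   partner groups by size is deliberately not done. Genes without a
   defined similarity (unannotated in the namespace) are skipped and the
   counts in the ratio follow the genes actually summed; an EC with no
   scorable gene is dropped from the report. The cap of 5 is applied
   after averaging. The RWR continuation and the smoothing constant are
   distinct parameters (`restart` vs `smoothing` on the command line)
   even though both are conventionally called c.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| continuation c | 0.7 | probability the walker follows an edge; restart 1−c = 0.3. A common network-propagation default; every invariant holds for any c ∈ (0,1), and c → 0 recovers the annotation-only measure. |
| z-threshold | 1.6 | standard-score cutoff for significant term pairs (two-sided). |
| background sample | 2000 | per-term background size cap; full background below it, seeded sample above. |
| LFC smoothing | 0.001 | Laplacian smoothing inside the log-ratio. |
| LFC cap | 5 | upper truncation of reported LFC scores. |
| iteration tol | 1e−10 | L1 stopping threshold of the power iteration. |

## Synthetic data: what it does and does not emulate

`make_fixture` generates a layered single-rooted DAG (each term takes 1–2
parents from the previous layer, all `is_a`), genes annotated clade-wise
to leaf-term blocks, a planted-partition network (intra-module edge
probability 0.6, inter 0.05, weights U(0.5, 1.5)), and EC groups. With
`aligned=True` the network modules, annotation clades and EC groups are
the same partition — the signal the benchmark is meant to detect. With
`aligned=False` the three are decoupled by independent permutations, a
null in which the median LFC should sit near zero. All randomness flows
through one `numpy` generator seeded from the spec; identical specs write
byte-identical files.

The generator emulates *structure*, not realism: GO's heavy-tailed term
degree distribution, annotation depth bias, evidence-code mixture and
shallow-annotation sparsity are all absent, and modules are equally sized.
Passing tests therefore demonstrate correctness of the computation and
the direction of the network's contribution on planted structure; they do
not certify effect sizes on real yeast or Arabidopsis data, whose inputs
(GO release, YeastNet/AraNet, curated EC lists) are external downloads.

The planted-structure comparison in the test suite and acceptance script
uses 30 modules of 4 genes over a 121-term, depth-4 DAG — large enough
for a 30-EC sign test while keeping the full pipeline (two runs plus a
shuffled null) around ten seconds. The network-off ablation sets
c = 1e−9, collapsing all cross-gene distances to 1.

## Numerical choices and degenerate inputs

- Duplicate network edges keep the maximum weight; self-loops are
  dropped; zero-degree genes are dropped at load (a zero column cannot be
  normalised) and fall back to the absent-gene distance of 1.
- Normalised distances are clipped to [0,1]; the term-similarity score is
  clamped at 0 against log rounding (analytically it is nonnegative).
- A pair of terms linked by both `is_a` and `part_of` keeps `is_a`.
- Multiple roots in a namespace are rejected — the score needs a single
  |G| normaliser.
- The walk's non-convergence (e.g. c close to 1 with a small iteration
  cap) raises with the last residual rather than returning a stale
  matrix.

## Known limitations

- Full pairwise term-similarity and background computation is quadratic
  in the number of annotated terms; real-ontology runs rely on the seeded
  background sampling and would benefit from persistent caching beyond
  the in-memory one provided.
- The |z| > 1.6 ⇔ p < 0.05 reading assumes the per-term background
  similarities are roughly normal; no normality check is enforced.
- Cross-namespace similarity, `regulates`-type edges, obsolete-term
  resolution and competing baseline measures (Resnik, Lin/Relevance,
  Wang) are out of scope; the annotation-only limit (c → 0, selection
  off) is exposed as a regression surface instead.
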