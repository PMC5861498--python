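# netsim2

Gene Ontology (GO)-based gene functional similarity that incorporates the
**global** topology of a gene co-functional network (YeastNet/AraNet-style
weighted edge lists) instead of only direct interactions. It is aimed at
computational biologists who need gene-to-gene functional similarities for
function prediction, network analysis, or benchmarking — especially for
organisms whose GO annotation is incomplete, where the co-functional
network carries much of the functional signal.

## The measure

Three stages:

**1. Gene relevance by random walk with restart (RWR).** Given the
column-normalised weight matrix M′ of the network, the walker update is
r ← cM′r + (1−c)eᵢ, with continuation probability c (restart 1−c; default
c = 0.7). Its fixed point rᵢ = (1−c)(I − cM′)⁻¹eᵢ fills a relevance matrix
R; the gene distance is dᵢⱼ = 1 − sym(R)ᵢⱼ, dᵢᵢ = 0, and genes outside the
network are at distance 1.

**2. Term similarity through path-constrained annotation.** For terms
t₁, t₂ with propagated gene sets G₁, G₂, the gene-set distance

D(t₁,t₂) = (Σ_{i∈G₁}Π_{j∈G₂}dᵢⱼ + Σ_{i∈G₂}Π_{j∈G₁}dᵢⱼ) / (2|G₁∪G₂| − Σ − Σ)

is min–max normalised to [0,1] over all computed term pairs. For each
lowest common ancestor p, with U(t₁,t₂,p) the genes annotated to t₁, t₂ or
directly to any term on a directed path from t₁ or t₂ up to p:

- f = D²·|U| + (1−D²)·√(|G₁||G₂|)
- h = D²·|G| + (1−D²)·max(|G₁|,|G₂|)
- S_p = [2log|G| − 2log f] / [2log|G| − log|G₁| − log|G₂|] · (1 − (h/|G|)(|G_p|/|G|))

and S(t₁,t₂) is the maximum S_p over all lowest common ancestors (GO is a
DAG; there can be several).

**3. Gene similarity from significant term pairs.** Each term t has a
background mean μ_t and standard deviation σ_t of S(t,·) over all other
terms; the standard score z = (S−μ_t)/σ_t flags significant pairs at
|z| > 1.6. For a gene pair with direct annotation sets T_i, T_j, each term
selects the larger of the high/low significant subsets of the other gene's
terms (with a best-|z| fallback) and contributes its best match; GeneSim
is the two-directional average.

**Benchmark.** Genes sharing a full four-field Enzyme Commission (EC)
number are assumed functionally similar. The logged fold change
LFC(e_i) averages, over gene-disjoint partner groups e_j and genes
g ∈ G(e_i), the log-ratio of mean smoothed inter-group distance to mean
intra-group distance, capped at 5. Positive LFC means within-EC pairs look
more similar than between-EC pairs.

## Worked example

Everything runs offline: the `synthetic` module generates a toy ontology,
annotations, planted-partition network and EC groups.

```python
from netsim2 import FixtureSpec, make_fixture, relevance_matrix
from netsim2.termsim import TermSimilarityContext
from netsim2.genesim import TermBackground, GeneSimilarity
from netsim2.evaluation import lfc_report, quartile_summary

fx = make_fixture(FixtureSpec(seed=1))          # 15 terms, 30 genes, 3 modules
rel = relevance_matrix(fx.network, c=0.7)       # continuation c, restart 0.3
ctx = TermSimilarityContext(fx.dag, fx.annotations, rel)
bg = TermBackground.build(ctx)
sim = GeneSimilarity(fx.annotations, ctx, bg)

print("same-module pair:", round(sim("g0001", "g0002"), 4))
print("cross-module pair:", round(sim("g0001", "g0030"), 4))
report = lfc_report(fx.ec_groups, sim)
print(report.to_string(index=False))
print(quartile_summary(report).round(3).to_string())
```

prints

```
same-module pair: 0.8889
cross-module pair: 0.0854
     ec      lfc  n_genes  n_partners
1.1.1.1 2.119455       10           2
1.1.1.2 1.972909       10           2
1.1.1.3 1.768549       10           2
25%    1.871
50%    1.973
75%    2.046
```

Two genes from the same planted functional module score 0.89 while a
cross-module pair scores 0.09, and every EC group gets a clearly positive
LFC — within-EC similarity dominates between-EC similarity.

The same pipeline is available from the shell:

```
netsim2 synth --seed 1 --out-dir fixtures/
netsim2 evaluate --obo fixtures/fixture.obo --gaf fixtures/fixture.gaf \
    --network fixtures/network.tsv --ec fixtures/ec.tsv --out report.tsv
```

Other subcommands: `ontology stats`, `rwr`, `termsim`, `genesim`. Real GO
releases (OBO), GAF 2.x annotation files, and YeastNet/AraNet edge lists
are read directly by the same commands.

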