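"""Shared fixtures: tiny hand-built ontologies and a small synthetic run."""

import numpy as np
import pytest

from netsim2.genesim import GeneSimilarity, TermBackground
from netsim2.network import relevance_matrix
from netsim2.ontology import AnnotationMap, OntologyDAG
from netsim2.synthetic import FixtureSpec, make_fixture
from netsim2.termsim import TermSimilarityContext


@pytest.fixture
def chain_dag():
    """root <- A <- B, all is_a."""
    return OntologyDAG.from_edges(
        ["root", "A", "B"], [("A", "root", "is_a"), ("B", "A", "is_a")], "MF"
    )


@pytest.fixture
def diamond_dag():
    """Two incomparable parents p1, p2 over children c1, c2 under one root."""
    edges = [
        ("p1", "root", "is_a"),
        ("p2", "root", "is_a"),
        ("c1", "p1", "is_a"),
        ("c1", "p2", "is_a"),
        ("c2", "p1", "is_a"),
        ("c2", "p2", "part_of"),
    ]
    return OntologyDAG.from_edges(["root", "p1", "p2", "c1", "c2"], edges, "MF")


def random_dag(rng, n_terms):
    """Random single-rooted DAG: term k > 0 gets 1-3 parents among 0..k-1."""
    terms = [f"T{k}" for k in range(n_terms)]
    edges = []
    for k in range(1, n_terms):
        n_parents = int(rng.integers(1, min(3, k) + 1))
        for p in rng.choice(k, size=n_parents, replace=False):
            edges.append((terms[k], terms[int(p)], "is_a"))
    return OntologyDAG.from_edges(terms, edges, "MF")


def random_annotations(rng, dag, n_genes):
    """Each gene directly annotated to 1-3 random terms."""
    terms = sorted(dag.terms)
    direct = {}
    for i in range(n_genes):
        k = int(rng.integers(1, 4))
        direct[f"g{i}"] = set(
            terms[int(j)] for j in rng.choice(len(terms), size=k, replace=False)
        )
    return AnnotationMap.from_direct(dag, direct)


@pytest.fixture(scope="session")
def small_fixture():
    """Aligned synthetic fixture, pipeline-sized for unit tests."""
    return make_fixture(
        FixtureSpec(seed=7, n_terms=31, depth=3, branching=3, n_genes=40, n_modules=4)
    )


@pytest.fixture(scope="session")
def small_pipeline(small_fixture):
    """(fixture, relevance, context, background, genesim) ready to query."""
    fx = small_fixture
    rel = relevance_matrix(fx.network, c=0.7)
    ctx = TermSimilarityContext(fx.dag, fx.annotations, rel)
    bg = TermBackground.build(ctx)
    simfn = GeneSimilarity(fx.annotations, ctx, bg)
    return fx, rel, ctx, bg, simfn
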