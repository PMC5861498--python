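"""Gene Ontology DAG handling and annotation propagation.

This module holds the structural side of the similarity measure: a single
GO namespace restricted to ``is_a`` and ``part_of`` edges, gene annotations
parsed from GAF files, true-path propagation of annotations up the DAG,
lowest-common-ancestor queries, and the *path-constrained* annotation sets
that replace the full descendant closure of a common ancestor when scoring
a term pair.

Edges are stored child -> parent, so "ancestors" of a term are the terms
reachable by following edges forward. A term counts among its own ancestors
(and descendants); this makes ``lowest_common_ancestors(t, t) == {t}`` and
keeps self-similarity well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

#: The only edge labels this tool keeps.
KEPT_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACE_ALIASES = {
    "mf": "molecular_function",
    "bp": "biological_process",
    "cc": "cellular_component",
    "molecular_function": "molecular_function",
    "biological_process": "biological_process",
    "cellular_component": "cellular_component",
}


class OntologyError(ValueError):
    """Structural problem with the ontology (cycle, multiple roots, ...)."""


class UnknownTermError(KeyError):
    """A query names a term that is not in the DAG."""


def resolve_namespace(name: str) -> str:
    try:
        return NAMESPACE_ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown namespace {name!r}; expected one of "
            "molecular_function/biological_process/cellular_component (or MF/BP/CC)"
        ) from None


class OntologyDAG:
    """One GO namespace as a rooted DAG of is_a / part_of edges.

    Parameters
    ----------
    graph
        Directed graph with child -> parent edges; each edge carries a
        ``relation`` attribute, either ``"is_a"`` or ``"part_of"``.
    namespace
        Canonical namespace name.
    """

    def __init__(self, graph: nx.DiGraph, namespace: str) -> None:
        self.graph = graph
        self.namespace = resolve_namespace(namespace)
        self._validate()
        # single sink == root (validated)
        self.root = next(n for n in graph.nodes if graph.out_degree(n) == 0)

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        terms: Iterable[str],
        edges: Iterable[tuple[str, str, str]],
        namespace: str,
    ) -> "OntologyDAG":
        """Build from (child, parent, relation) triples plus isolated terms."""
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for child, parent, rel in edges:
            if rel not in KEPT_RELATIONS:
                raise OntologyError(f"unsupported edge label {rel!r}")
            g.add_edge(child, parent, relation=rel)
        return cls(g, namespace)

    def _validate(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise OntologyError("empty ontology")
        for _, _, rel in self.graph.edges(data="relation"):
            if rel not in KEPT_RELATIONS:
                raise OntologyError(f"unsupported edge label {rel!r}")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology graph contains a cycle through {cycle[0][0]}")
        roots = [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise OntologyError(
                f"expected a single root for the namespace, found {len(roots)}: "
                f"{sorted(roots)[:5]}"
            )

    # -- queries ------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def _check(self, term: str) -> None:
        if term not in self.graph:
            raise UnknownTermError(term)

    def parents(self, term: str) -> set[str]:
        self._check(term)
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        self._check(term)
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """Terms reachable upward (toward the root); inclusive by default."""
        self._check(term)
        anc = nx.descendants(self.graph, term)  # edges point child -> parent
        if include_self:
            anc.add(term)
        return anc

    def descendants(self, term: str, include_self: bool = True) -> set[str]:
        self._check(term)
        desc = nx.ancestors(self.graph, term)
        if include_self:
            desc.add(term)
        return desc

    def lowest_common_ancestors(self, t1: str, t2: str) -> set[str]:
        """All common ancestors with no *proper* descendant that is also one.

        GO namespaces are DAGs, not trees, so a pair can have several
        incomparable lowest common ancestors; the similarity measure takes
        the maximum score over all of them.
        """
        common = self.ancestors(t1) & self.ancestors(t2)
        return {
            p
            for p in common
            if not (self.descendants(p, include_self=False) & common)
        }

    def topological_order(self) -> list[str]:
        """Terms ordered children before parents."""
        return list(nx.topological_sort(self.graph))


def parse_obo(path, namespace: str) -> OntologyDAG:
    """Read an OBO file, keeping one namespace and is_a/part_of edges only.

    Obsolete terms are dropped (obonet's default); edges with other labels
    (``regulates`` etc.) and cross-namespace edges are discarded. A cycle in
    the retained edges is a format error.
    """
    namespace = resolve_namespace(namespace)
    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        if data.get("namespace") == namespace:
            g.add_node(node)
    for child, parent, rel in multi.edges(keys=True):
        if rel in KEPT_RELATIONS and child in g and parent in g:
            # a pair linked by both is_a and part_of keeps is_a
            if not (g.has_edge(child, parent) and g[child][parent]["relation"] == "is_a"):
                g.add_edge(child, parent, relation=rel)
    if g.number_of_nodes() == 0:
        raise OntologyError(f"no terms in namespace {namespace!r} in {path}")
    return OntologyDAG(g, namespace)


@dataclass
class AnnotationMap:
    """Gene <-> term annotations, direct and true-path propagated.

    ``propagated[t]`` is the set of genes annotated to ``t`` or to any of
    its descendants; ``propagated[root]`` is the full annotated gene
    universe G that normalises the similarity formula.
    """

    direct: dict[str, frozenset[str]]  # gene -> terms
    direct_by_term: dict[str, frozenset[str]]  # term -> genes (direct only)
    propagated: dict[str, frozenset[str]]  # term -> genes (true-path)
    gene_universe: frozenset[str]
    n_skipped_unknown_term: int = 0
    n_skipped_not: int = 0
    n_skipped_malformed: int = 0

    @classmethod
    def from_direct(
        cls, dag: OntologyDAG, direct: Mapping[str, Iterable[str]], **counts
    ) -> "AnnotationMap":
        clean: dict[str, frozenset[str]] = {}
        for gene, terms in direct.items():
            ts = frozenset(terms)
            unknown = ts - dag.terms
            if unknown:
                raise UnknownTermError(sorted(unknown)[0])
            if ts:
                clean[gene] = ts
        prop = propagate(dag, clean)
        by_term: dict[str, set[str]] = {t: set() for t in dag.terms}
        for gene, ts in clean.items():
            for t in ts:
                by_term[t].add(gene)
        return cls(
            direct=clean,
            direct_by_term={t: frozenset(gs) for t, gs in by_term.items()},
            propagated=prop,
            gene_universe=frozenset(g for gs in prop.values() for g in gs),
            **counts,
        )

    def genes_of(self, term: str) -> frozenset[str]:
        return self.propagated[term]


def propagate(
    dag: OntologyDAG, direct: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """True-path rule: a gene annotated to a term annotates all its ancestors.

    Returns ``term -> genes`` where the gene set of a term is the union of
    direct annotations over the term and all of its descendants. Monotone
    along edges: ``propagated[child] <= propagated[parent]``.
    """
    by_term: dict[str, set[str]] = {t: set() for t in dag.terms}
    for gene, terms in direct.items():
        for t in terms:
            if t not in by_term:
                raise UnknownTermError(t)
            by_term[t].add(gene)
    prop: dict[str, set[str]] = {}
    for t in dag.topological_order():  # children before parents
        acc = set(by_term[t])
        for child in dag.graph.predecessors(t):
            acc |= prop[child]
        prop[t] = acc
    return {t: frozenset(gs) for t, gs in prop.items()}


def parse_gaf(
    path,
    dag: OntologyDAG,
    evidence_codes: Iterable[str] | None = None,
    id_field: str = "DB_Object_Symbol",
) -> AnnotationMap:
    """Read a GAF 2.x file into an :class:`AnnotationMap`.

    Rows whose term is outside the DAG (other namespaces, obsolete ids) are
    skipped with a logged count, as are NOT-qualified rows and malformed
    lines. All evidence codes are accepted unless an allow-list is given.

    Parameters
    ----------
    evidence_codes
        Optional allow-list of GAF evidence codes (e.g. ``{"EXP", "IDA"}``).
    id_field
        GAF column used as the gene identifier; the object symbol by
        default, which matches how co-functional networks name genes.
    """
    allow = frozenset(evidence_codes) if evidence_codes is not None else None
    direct: dict[str, set[str]] = {}
    n_unknown = n_not = n_malformed = 0
    with open(path) as handle:
        for rec in GOA.gafiterator(handle):
            try:
                gene = rec[id_field] or rec["DB_Object_ID"]
                term = rec["GO_ID"]
                qualifiers = rec.get("Qualifier") or []
                evidence = rec.get("Evidence")
            except (KeyError, TypeError):
                n_malformed += 1
                continue
            if not gene or not term:
                n_malformed += 1
                continue
            if any(q == "NOT" or q.startswith("NOT|") for q in qualifiers):
                n_not += 1
                continue
            if allow is not None and evidence not in allow:
                continue
            if term not in dag:
                n_unknown += 1
                continue
            direct.setdefault(gene, set()).add(term)
    if not direct:
        raise ValueError(f"no usable annotation rows in {path}")
    if n_unknown or n_not or n_malformed:
        logger.info(
            "GAF %s: skipped %d unknown-term, %d NOT-qualified, %d malformed rows",
            path, n_unknown, n_not, n_malformed,
        )
    return AnnotationMap.from_direct(
        dag,
        direct,
        n_skipped_unknown_term=n_unknown,
        n_skipped_not=n_not,
        n_skipped_malformed=n_malformed,
    )


def path_constrained_genes(
    dag: OntologyDAG, ann: AnnotationMap, t1: str, t2: str, p: str
) -> frozenset[str]:
    """The path-constrained annotation set U(t1, t2, p).

    Genes annotated (propagated) to t1 or t2, plus genes *directly*
    annotated to any term lying on a directed path from t1 to p or from t2
    to p (inclusive of the endpoints, so p's own direct genes count).
    Replaces the full descendant closure of the common ancestor, keeping
    only the annotation mass relevant to the compared terms; always
    satisfies G1 | G2 <= U <= G_p.
    """
    for t in (t1, t2, p):
        dag._check(t)
    if p not in dag.ancestors(t1) or p not in dag.ancestors(t2):
        raise ValueError(f"{p} is not a common ancestor of {t1} and {t2}")
    below_p = dag.descendants(p)  # inclusive
    # x on a directed t->p path  <=>  x ancestor-or-self of t and
    # descendant-or-self of p (paths compose through x in a DAG)
    path_terms = (dag.ancestors(t1) & below_p) | (dag.ancestors(t2) & below_p)
    genes = set(ann.propagated[t1]) | set(ann.propagated[t2])
    for x in path_terms:
        genes |= ann.direct_by_term[x]
    return frozenset(genes)
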