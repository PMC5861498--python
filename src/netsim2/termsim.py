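"""Term-term semantic similarity combining annotations and network distances.

The gene-set distance D(t1, t2) compares the genes annotated to two terms
through the RWR gene distances d_ij:

    D = (A + B) / (2 |G1 u G2| - A - B),
    A = sum_{i in G1} prod_{j in G2} d_ij,   B = sum_{i in G2} prod_{j in G1} d_ij

Shared genes zero the products (d_ii = 0), so D(G, G) = 0 and the
denominator is strictly positive for nonempty sets. Raw distances over all
computed term pairs are min-max normalised into [0, 1].

Term similarity then blends annotation counts with the normalised distance:

    f(t1,t2,p) = D^2 |U| + (1 - D^2) sqrt(|G1| |G2|)
    h(t1,t2)   = D^2 |G| + (1 - D^2) max(|G1|, |G2|)
    S_p = (2 log|G| - 2 log f) / (2 log|G| - log|G1| - log|G2|)
          * (1 - h/|G| * |G_p|/|G|)

with U the path-constrained annotation set of the common ancestor p, and
the final S(t1, t2) the maximum of S_p over all lowest common ancestors.
When the network is uninformative (all cross-gene distances equal) the
measure collapses toward annotation-only similarity.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Iterable, Mapping

import numpy as np

from .network import RelevanceMatrix
from .ontology import AnnotationMap, OntologyDAG, path_constrained_genes


class EmptyGeneSetError(ValueError):
    """A term with no propagated annotations has no defined similarity."""


def _sum_of_products(d: np.ndarray) -> float:
    """sum over rows of the product across columns, in log space.

    Factors are distances in [0, 1]; a zero anywhere in a row
    short-circuits that row's product to 0.
    """
    if d.size == 0:
        return 0.0
    zero_rows = (d <= 0.0).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(d > 0.0, np.log(d), 0.0).sum(axis=1)
    prods = np.where(zero_rows, 0.0, np.exp(logs))
    return float(prods.sum())


def gene_set_distance(
    g1: Iterable[str],
    g2: Iterable[str],
    dist: Callable[[str, str], float],
) -> float:
    """Raw (unnormalised) gene-set distance between two annotation sets."""
    s1, s2 = sorted(set(g1)), sorted(set(g2))
    if not s1 or not s2:
        raise EmptyGeneSetError("gene sets must be nonempty")
    d = np.array([[dist(a, b) for b in s2] for a in s1], dtype=float)
    a = _sum_of_products(d)
    b = _sum_of_products(d.T)
    union = len(set(s1) | set(s2))
    return (a + b) / (2.0 * union - a - b)


def normalize_distances(raw: Mapping) -> dict:
    """Min-max rescale raw distances to [0, 1] over all computed pairs.

    If every raw value is equal the span is degenerate and everything maps
    to 0 (network treated as uninformative).
    """
    values = list(raw.values())
    lo, hi = min(values), max(values)
    if hi - lo == 0:
        return {k: 0.0 for k in raw}
    return {k: (v - lo) / (hi - lo) for k, v in raw.items()}


def path_constrained_f(d_norm: float, u_size: int, g1_size: int, g2_size: int) -> float:
    """Blend of the path-constrained count |U| and sqrt(|G1||G2|) by D^2."""
    d2 = d_norm * d_norm
    return d2 * u_size + (1.0 - d2) * math.sqrt(g1_size * g2_size)


def parent_specificity_h(d_norm: float, g_size: int, g1_size: int, g2_size: int) -> float:
    """Blend of |G| and max(|G1|,|G2|) by D^2; specificity of the ancestor."""
    d2 = d_norm * d_norm
    return d2 * g_size + (1.0 - d2) * max(g1_size, g2_size)


def similarity_from_components(
    d_norm: float,
    u_size: int,
    g1_size: int,
    g2_size: int,
    gp_size: int,
    g_size: int,
) -> float:
    """Similarity score for one common ancestor from its size components.

    The left factor measures how far the pair sits below the ancestor
    (1 when f shrinks to sqrt(|G1||G2|), 0 when it reaches |G|); the right
    factor discounts unspecific ancestors close to the root. Both are
    base-invariant ratios of log differences, evaluated in natural log.
    When both terms annotate the whole genome the denominator vanishes and
    the similarity is defined as 0 — such terms carry no information.
    """
    denom = 2.0 * math.log(g_size) - (math.log(g1_size) + math.log(g2_size))
    if denom == 0.0:
        return 0.0
    f = path_constrained_f(d_norm, u_size, g1_size, g2_size)
    h = parent_specificity_h(d_norm, g_size, g1_size, g2_size)
    left = (2.0 * math.log(g_size) - 2.0 * math.log(f)) / denom
    right = 1.0 - (h / g_size) * (gp_size / g_size)
    # sqrt(|G1||G2|) <= f <= |G| analytically; clamp log rounding at 0
    return max(left * right, 0.0)


class TermSimilarityContext:
    """Precomputed gene-set distances and term similarities for one namespace.

    Built once from a DAG, its annotations and a relevance matrix; caches
    the raw pairwise gene-set distances over all eligible terms (those with
    nonempty propagated gene sets), the min-max normalisation bounds, and
    the symmetric term-similarity matrix. Normalisation bounds are fixed at
    build time so later queries are reproducible.
    """

    def __init__(
        self,
        dag: OntologyDAG,
        annotations: AnnotationMap,
        relevance: RelevanceMatrix,
        terms: list[str] | None = None,
    ) -> None:
        self.dag = dag
        self.annotations = annotations
        self.relevance = relevance
        if terms is None:
            terms = sorted(t for t in dag.terms if annotations.propagated[t])
        else:
            terms = sorted(terms)
            for t in terms:
                if not annotations.propagated[t]:
                    raise EmptyGeneSetError(f"term {t} has no annotated genes")
        self.terms = terms
        self._tindex = {t: k for k, t in enumerate(terms)}
        self._genes = sorted(annotations.gene_universe)
        gindex = {g: i for i, g in enumerate(self._genes)}
        self._gene_dist = relevance.distance_submatrix(self._genes)
        self._gene_sets = {
            t: np.array(sorted(gindex[g] for g in annotations.propagated[t]))
            for t in terms
        }
        self._raw = self._raw_distance_matrix()
        off_diag = self._raw[~np.eye(len(terms), dtype=bool)]
        if off_diag.size:
            self.raw_bounds = (float(off_diag.min()), float(off_diag.max()))
        else:
            self.raw_bounds = (0.0, 0.0)
        self._norm = self._normalize(self._raw)
        self._S: np.ndarray | None = None
        # ancestor / descendant closures reused across LCA queries
        self._anc = {t: dag.ancestors(t) for t in terms}

    # -- gene-set distances -------------------------------------------

    def _raw_pair(self, s1: np.ndarray, s2: np.ndarray) -> float:
        d = self._gene_dist[np.ix_(s1, s2)]
        a = _sum_of_products(d)
        b = _sum_of_products(d.T)
        union = len(np.union1d(s1, s2))
        return (a + b) / (2.0 * union - a - b)

    def _raw_distance_matrix(self) -> np.ndarray:
        n = len(self.terms)
        raw = np.zeros((n, n))
        sets = [self._gene_sets[t] for t in self.terms]
        for i, j in itertools.combinations(range(n), 2):
            raw[i, j] = raw[j, i] = self._raw_pair(sets[i], sets[j])
        return raw

    def _normalize(self, raw: np.ndarray) -> np.ndarray:
        lo, hi = self.raw_bounds
        if hi - lo == 0:
            return np.zeros_like(raw)
        norm = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
        np.fill_diagonal(norm, 0.0)  # raw self-distance is exactly 0
        return norm

    def _k(self, term: str) -> int:
        try:
            return self._tindex[term]
        except KeyError:
            raise EmptyGeneSetError(
                f"term {term} is not eligible (missing or unannotated)"
            ) from None

    def raw_distance(self, t1: str, t2: str) -> float:
        return float(self._raw[self._k(t1), self._k(t2)])

    def norm_distance(self, t1: str, t2: str) -> float:
        return float(self._norm[self._k(t1), self._k(t2)])

    # -- term similarity ----------------------------------------------

    def similarity_per_ancestor(self, t1: str, t2: str) -> dict[str, float]:
        """Score for every lowest common ancestor of the pair."""
        self._k(t1), self._k(t2)
        prop = self.annotations.propagated
        g_size = len(prop[self.dag.root])
        g1, g2 = len(prop[t1]), len(prop[t2])
        d = self.norm_distance(t1, t2)
        out: dict[str, float] = {}
        for p in self.dag.lowest_common_ancestors(t1, t2):
            u = len(path_constrained_genes(self.dag, self.annotations, t1, t2, p))
            out[p] = similarity_from_components(d, u, g1, g2, len(prop[p]), g_size)
        return out

    def similarity(self, t1: str, t2: str) -> float:
        """S(t1, t2): maximum score over all lowest common ancestors."""
        return max(self.similarity_per_ancestor(t1, t2).values())

    def similarity_matrix(self) -> np.ndarray:
        """Symmetric matrix of S over all eligible terms (cached)."""
        if self._S is None:
            n = len(self.terms)
            s = np.zeros((n, n))
            for i, j in itertools.combinations_with_replacement(range(n), 2):
                s[i, j] = s[j, i] = self.similarity(self.terms[i], self.terms[j])
            self._S = s
        return self._S

    def similarity_lookup(self) -> Callable[[str, str], float]:
        s = self.similarity_matrix()
        return lambda t1, t2: float(s[self._k(t1), self._k(t2)])
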