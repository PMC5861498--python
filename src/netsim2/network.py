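"""Co-functional network loading and random walk with restart (RWR).

The relevance of gene j to gene i is the stationary probability that a
random walker started at i, following edges with probability proportional
to their weights and restarting at i with probability (1 - c), is found at
j. Collecting these for all start genes gives the relevance matrix R; the
gene-gene distance used downstream is d_ij = 1 - R_ij after symmetrising R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Default continuation probability c; the restart probability is 1 - c.
DEFAULT_CONTINUATION = 0.7

#: Above this size the dense closed-form solve gives way to iteration.
DENSE_SOLVE_LIMIT = 2000


class NetworkFormatError(ValueError):
    """Malformed edge list (negative weight, empty graph, ...)."""


class ConvergenceError(RuntimeError):
    def __init__(self, iterations: int, residual: float):
        super().__init__(
            f"RWR iteration did not converge in {iterations} iterations "
            f"(last L1 residual {residual:.3g})"
        )
        self.iterations = iterations
        self.residual = residual


@dataclass
class CoFunctionalNetwork:
    """Weighted undirected gene graph with a fixed gene ordering.

    ``weights`` is symmetric, nonnegative, zero-diagonal; a zero entry
    means no edge. Zero-degree genes are never admitted (they would break
    the column normalisation) — they fall back to the absent-gene distance
    of 1 downstream.
    """

    genes: list[str]
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.weights.shape != (n, n):
            raise ValueError("weights shape does not match gene list")
        self.index = {g: i for i, g in enumerate(self.genes)}

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str, float]]
    ) -> "CoFunctionalNetwork":
        """Build from (geneA, geneB, weight) triples.

        Duplicate edges keep the maximum weight; self-loops and
        non-positive-weight edges are dropped (negative weights are a
        format error); genes left with no edge are dropped with a log line.
        """
        best: dict[tuple[str, str], float] = {}
        dropped_isolated: set[str] = set()
        for a, b, w in edges:
            if w < 0:
                raise NetworkFormatError(f"negative edge weight {w} on {a}--{b}")
            if a == b:
                continue
            if w == 0:
                dropped_isolated.update((a, b))
                continue
            key = (a, b) if a < b else (b, a)
            if w > best.get(key, 0.0):
                best[key] = w
        genes = sorted({g for pair in best for g in pair})
        if not genes:
            raise NetworkFormatError("network has no usable edges")
        dropped_isolated -= set(genes)
        if dropped_isolated:
            logger.info("dropped %d zero-degree genes", len(dropped_isolated))
        index = {g: i for i, g in enumerate(genes)}
        rows, cols, vals = [], [], []
        for (a, b), w in best.items():
            i, j = index[a], index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        weights = sp.csr_matrix((vals, (rows, cols)), shape=(len(genes), len(genes)))
        return cls(genes=genes, weights=weights)

    @property
    def n_edges(self) -> int:
        return self.weights.nnz // 2

    def __contains__(self, gene: str) -> bool:
        return gene in self.index


def load_network(path) -> CoFunctionalNetwork:
    """Read a YeastNet/AraNet-style edge list: geneA TAB geneB TAB weight.

    Extra columns are ignored; ``#`` lines are comments. Negative weights
    are a format error; an empty usable graph is an error.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise NetworkFormatError(f"{path}:{lineno}: expected >=3 columns")
            a, b, w_str = fields[0], fields[1], fields[2]
            try:
                w = float(w_str)
            except ValueError:
                raise NetworkFormatError(
                    f"{path}:{lineno}: non-numeric weight {w_str!r}"
                ) from None
            edges.append((a, b, w))
    if not edges:
        raise NetworkFormatError(f"{path}: no edges")
    return CoFunctionalNetwork.from_edges(edges)


def normalize(network: CoFunctionalNetwork) -> sp.csc_matrix:
    """Column-stochastic transition matrix M'[i, j] = M[i, j] / sum_k M[k, j]."""
    m = network.weights.tocsc().astype(float)
    colsums = np.asarray(m.sum(axis=0)).ravel()
    if np.any(colsums <= 0):
        bad = network.genes[int(np.argmin(colsums))]
        raise NetworkFormatError(f"gene {bad} has zero total edge weight")
    return m @ sp.diags(1.0 / colsums)


@dataclass
class RelevanceMatrix:
    """Gene-gene stationary probabilities from RWR.

    Row i holds the stationary distribution of the walk restarted at gene
    i; every row sums to 1. ``distance`` symmetrises R before converting
    to a distance, because the walk on a weighted graph is asymmetric while
    the gene-set distance needs a symmetric d_ij.
    """

    genes: list[str]
    R: np.ndarray
    continuation: float

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.genes)}

    @cached_property
    def _sym_distance(self) -> np.ndarray:
        d = 1.0 - 0.5 * (self.R + self.R.T)
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)

    def distance(self, g_i: str, g_j: str) -> float:
        """d_ij = 1 - sym(R)_ij; 0 on the diagonal, 1 for absent genes."""
        if g_i == g_j:
            return 0.0
        i = self.index.get(g_i)
        j = self.index.get(g_j)
        if i is None or j is None:
            return 1.0
        return float(self._sym_distance[i, j])

    def distance_submatrix(self, genes: list[str]) -> np.ndarray:
        """Symmetric distance matrix over an arbitrary gene list.

        Genes absent from the network get distance 1 to everything except
        themselves.
        """
        n = len(genes)
        d = np.ones((n, n))
        present = [(k, self.index[g]) for k, g in enumerate(genes) if g in self.index]
        if present:
            ks = np.array([k for k, _ in present])
            js = np.array([j for _, j in present])
            d[np.ix_(ks, ks)] = self._sym_distance[np.ix_(js, js)]
        np.fill_diagonal(d, 0.0)
        return d


def _check_continuation(c: float) -> None:
    if not 0.0 < c < 1.0:
        raise ValueError(f"continuation probability must be in (0, 1), got {c}")


def rwr_closed_form(
    mprime: sp.spmatrix, c: float, genes: list[str]
) -> RelevanceMatrix:
    """Exact stationary distributions: r_i = (1-c) (I - c M')^-1 e_i.

    Solved densely; for column-stochastic M' and c < 1 the inverse always
    exists and each r_i is a probability vector.
    """
    _check_continuation(c)
    n = mprime.shape[0]
    a = np.eye(n) - c * np.asarray(mprime.todense())
    inv = np.linalg.solve(a, np.eye(n))
    r = (1.0 - c) * inv.T  # row i is the start-at-i distribution
    return RelevanceMatrix(genes=list(genes), R=r, continuation=c)


def rwr_iterative(
    mprime: sp.spmatrix,
    c: float,
    genes: list[str],
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> RelevanceMatrix:
    """Power iteration r <- c M' r + (1-c) e_i for all starts at once.

    Stops when the largest per-column L1 change drops below ``tol``; the
    contraction factor c then bounds the L1 distance to the closed-form
    solution by tol / (1 - c).
    """
    _check_continuation(c)
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = mprime.shape[0]
    restart = (1.0 - c) * np.eye(n)
    x = np.eye(n)  # column k is the walk started at gene k
    residual = np.inf
    for _ in range(max_iter):
        x_new = c * (mprime @ x) + restart
        residual = float(np.max(np.abs(x_new - x).sum(axis=0)))
        x = x_new
        if residual < tol:
            return RelevanceMatrix(genes=list(genes), R=x.T, continuation=c)
    raise ConvergenceError(max_iter, residual)


def relevance_matrix(
    network: CoFunctionalNetwork,
    c: float = DEFAULT_CONTINUATION,
    method: str = "auto",
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> RelevanceMatrix:
    """Compute R for a network; closed form for small graphs, iterative above."""
    mprime = normalize(network)
    if method == "auto":
        method = "closed" if len(network.genes) <= DENSE_SOLVE_LIMIT else "iterative"
    if method == "closed":
        return rwr_closed_form(mprime, c, network.genes)
    if method == "iterative":
        return rwr_iterative(mprime, c, network.genes, tol=tol, max_iter=max_iter)
    raise ValueError(f"unknown method {method!r}")
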