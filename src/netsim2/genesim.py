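"""Gene-gene similarity via significant term-pair selection.

Considering indirect network neighbours enriches the term similarities but
also imports noise; this module filters it out before aggregating to the
gene level. For each term t a background of similarities S(t, t') over all
other eligible terms gives a mean mu_t and (population) standard deviation
sigma_t; the standard score z = (S - mu_t) / sigma_t flags significant
term pairs at |z| > 1.6 (p < 0.05 under a normal background).

For a gene pair (g_i, g_j) with direct annotation sets T_i and T_j, each
term t in T_i selects a significant subset T'_j of T_j (the larger of the
high set {z > 1.6} and the low set {z < -1.6}); its contribution is the
best match max_{t' in T'_j} S(t, t'). The gene similarity averages both
directions:

    GeneSim = (sum_{t in T_i} Sim(t, T'_j) + sum_{t in T_j} Sim(t, T'_i))
              / (|T_i| + |T_j|)

With selection disabled (T' = the full annotation set) this reduces to the
classic best-match average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .ontology import AnnotationMap
from .termsim import TermSimilarityContext

Z_THRESHOLD = 1.6


class DegenerateBackgroundError(ValueError):
    """sigma_t = 0: every background similarity identical."""


class UnannotatedGeneError(KeyError):
    def __init__(self, gene: str):
        super().__init__(f"gene {gene} has no direct annotation in this namespace")
        self.gene = gene


@dataclass(frozen=True)
class BackgroundEntry:
    mean: float
    std: float
    n: int


def term_background(
    ctx: TermSimilarityContext, t: str, background: Sequence[str]
) -> BackgroundEntry:
    """Mean / population-std of S(t, t') over a background term set.

    ``background`` is T_G without t, or a seeded uniform sample of it.
    """
    background = [b for b in background if b != t]
    if len(background) < 2:
        raise ValueError("background must contain at least 2 terms")
    s = ctx.similarity_matrix()
    k = ctx._k(t)
    vals = s[k, [ctx._k(b) for b in background]]
    return BackgroundEntry(mean=float(vals.mean()), std=float(vals.std()), n=len(vals))


class TermBackground:
    """Per-term background statistics for the whole eligible term set."""

    def __init__(self, entries: dict[str, BackgroundEntry]):
        self.entries = entries

    def __getitem__(self, term: str) -> BackgroundEntry:
        return self.entries[term]

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    @classmethod
    def build(
        cls,
        ctx: TermSimilarityContext,
        sample_size: int | None = None,
        seed: int | None = None,
    ) -> "TermBackground":
        """Backgrounds for every eligible term.

        Uses the full T_G \\ {t} by default; for large ontologies a seeded
        uniform sample of ``sample_size`` terms keeps the cost bounded
        while staying deterministic.
        """
        terms = ctx.terms
        rng = np.random.default_rng(seed)
        entries: dict[str, BackgroundEntry] = {}
        for t in terms:
            others = [b for b in terms if b != t]
            if sample_size is not None and len(others) > sample_size:
                pick = rng.choice(len(others), size=sample_size, replace=False)
                others = [others[i] for i in sorted(pick)]
            entries[t] = term_background(ctx, t, others)
        return cls(entries)


def z_score(s_val: float, bg: BackgroundEntry) -> float:
    """Standard score of a similarity against a term's background."""
    if bg.std == 0:
        raise DegenerateBackgroundError("background standard deviation is 0")
    return (s_val - bg.mean) / bg.std


def select_significant_set(
    t: str,
    candidates: Sequence[str],
    sim: Callable[[str, str], float],
    bg: TermBackground,
    z_threshold: float = Z_THRESHOLD,
) -> tuple[str, ...]:
    """Significant subset of ``candidates`` for term t.

    The high set {t' : z > threshold} wins if strictly larger than the low
    set {t' : z < -threshold}; the low set wins if strictly larger; a
    nonempty tie goes to the high set (similarity aggregation favours
    informative matches). If neither is populated the single candidate
    with the largest |z| is returned, so every term can form a significant
    pair. A degenerate background (sigma = 0) falls back to the highest-S
    candidate.
    """
    if not candidates:
        raise ValueError("candidate set must be nonempty")
    entry = bg[t]
    svals = [sim(t, c) for c in candidates]
    if entry.std == 0:
        return (candidates[int(np.argmax(svals))],)
    z = [(s - entry.mean) / entry.std for s in svals]
    high = tuple(c for c, zv in zip(candidates, z) if zv > z_threshold)
    low = tuple(c for c, zv in zip(candidates, z) if zv < -z_threshold)
    if len(high) > len(low):
        return high
    if len(low) > len(high):
        return low
    if high:  # equal nonzero sizes: prefer the high-similarity set
        return high
    return (candidates[int(np.argmax(np.abs(z)))],)


@dataclass
class GenePairResult:
    """GeneSim for one gene pair with its per-term evidence."""

    gene_i: str
    gene_j: str
    value: float
    terms_i: tuple[str, ...]
    terms_j: tuple[str, ...]
    selected_for_i: dict[str, tuple[str, ...]]  # t in T_i -> T'_j used
    selected_for_j: dict[str, tuple[str, ...]]  # t in T_j -> T'_i used
    best_match_i: dict[str, float]  # t in T_i -> Sim(t, T'_j)
    best_match_j: dict[str, float]


def _direct_terms(
    gene: str, ann: AnnotationMap, ctx: TermSimilarityContext
) -> tuple[str, ...]:
    terms = ann.direct.get(gene, frozenset()) & set(ctx.terms)
    if not terms:
        raise UnannotatedGeneError(gene)
    return tuple(sorted(terms))


def gene_similarity(
    g_i: str,
    g_j: str,
    ann: AnnotationMap,
    ctx: TermSimilarityContext,
    bg: TermBackground,
    z_threshold: float = Z_THRESHOLD,
    select: bool = True,
) -> GenePairResult:
    """GeneSim between two genes from their direct annotation sets.

    Direct (not propagated) annotations are used: averaging over ancestor
    closures would drown the specific terms in generic ones. ``select=False``
    disables significant-pair selection (T' = full set), giving the plain
    best-match average used as the annotation-only baseline.
    """
    t_i = _direct_terms(g_i, ann, ctx)
    t_j = _direct_terms(g_j, ann, ctx)
    sim = ctx.similarity_lookup()

    def one_direction(ts: Sequence[str], candidates: Sequence[str]):
        selected: dict[str, tuple[str, ...]] = {}
        best: dict[str, float] = {}
        for t in ts:
            chosen = (
                select_significant_set(t, candidates, sim, bg, z_threshold)
                if select
                else tuple(candidates)
            )
            selected[t] = chosen
            best[t] = max(sim(t, c) for c in chosen)
        return selected, best

    sel_i, best_i = one_direction(t_i, t_j)
    sel_j, best_j = one_direction(t_j, t_i)
    value = (sum(best_i.values()) + sum(best_j.values())) / (len(t_i) + len(t_j))
    return GenePairResult(
        gene_i=g_i,
        gene_j=g_j,
        value=value,
        terms_i=t_i,
        terms_j=t_j,
        selected_for_i=sel_i,
        selected_for_j=sel_j,
        best_match_i=best_i,
        best_match_j=best_j,
    )


class GeneSimilarity:
    """Callable GeneSim over many pairs with selection caching.

    Selection depends only on (t, candidate set), so results are cached
    across gene pairs; genes without annotations yield ``None`` rather
    than raising, which lets the benchmark skip and count them.
    """

    def __init__(
        self,
        ann: AnnotationMap,
        ctx: TermSimilarityContext,
        bg: TermBackground,
        z_threshold: float = Z_THRESHOLD,
        select: bool = True,
    ) -> None:
        self.ann = ann
        self.ctx = ctx
        self.bg = bg
        self.z_threshold = z_threshold
        self.select = select
        self._sim = ctx.similarity_lookup()
        self._sel_cache: dict[tuple[str, tuple[str, ...]], tuple[str, ...]] = {}
        self._term_cache: dict[str, tuple[str, ...]] = {}

    def _terms(self, gene: str) -> tuple[str, ...] | None:
        if gene not in self._term_cache:
            terms = self.ann.direct.get(gene, frozenset()) & set(self.ctx.terms)
            self._term_cache[gene] = tuple(sorted(terms))
        return self._term_cache[gene] or None

    def _best(self, t: str, candidates: tuple[str, ...]) -> float:
        if self.select:
            key = (t, candidates)
            if key not in self._sel_cache:
                self._sel_cache[key] = select_significant_set(
                    t, candidates, self._sim, self.bg, self.z_threshold
                )
            chosen = self._sel_cache[key]
        else:
            chosen = candidates
        return max(self._sim(t, c) for c in chosen)

    def __call__(self, g_i: str, g_j: str) -> float | None:
        t_i = self._terms(g_i)
        t_j = self._terms(g_j)
        if t_i is None or t_j is None:
            return None
        fwd = sum(self._best(t, t_j) for t in t_i)
        bwd = sum(self._best(t, t_i) for t in t_j)
        return (fwd + bwd) / (len(t_i) + len(t_j))

    def matrix(self, genes: Sequence[str]) -> "np.ndarray":
        """Symmetric GeneSim matrix over a gene list (NaN where undefined)."""
        n = len(genes)
        out = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i, n):
                v = self(genes[i], genes[j])
                if v is not None:
                    out[i, j] = out[j, i] = v
        return out
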