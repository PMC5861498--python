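"""Enzyme-Commission benchmark: the logged fold change (LFC) statistic.

Genes sharing a full four-field EC number are assumed functionally
similar. For a gene g in group G(e_i) and a disjoint group G(e_j), the
diff score contrasts the mean smoothed distance to the foreign group with
the mean smoothed distance to g's own group:

    diff_g(e_i, e_j) = ln[ |G(e_i) \\ g| * sum_{g' in G(e_j)} (1 - sim + c)
                         / (|G(e_j)| * sum_{g* in G(e_i) \\ g} (1 - sim + c)) ]

(c is a Laplacian smoothing constant preventing ln 0 at similarity 1; the
"without g" convention applies to both the count and the sum). diff > 0
means g sits closer to its own EC group than to e_j. The LFC of e_i
averages diff over the group's genes and then over all disjoint partner
groups, capped at 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log
from typing import Callable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING = 0.001
DEFAULT_CAP = 5.0

SimilarityFn = Callable[[str, str], "float | None"]


class ECFormatError(ValueError):
    pass


class UndefinedScoreError(ValueError):
    """No disjoint partner EC, or no scorable gene, for this group."""


@dataclass
class ECGroups:
    """Mapping from full four-field EC numbers to gene sets (size >= 2)."""

    groups: dict[str, frozenset[str]]
    n_dropped_partial: int = 0
    n_dropped_small: int = 0

    def __post_init__(self) -> None:
        for ec, genes in self.groups.items():
            if len(ec.split(".")) != 4:
                raise ECFormatError(f"EC number {ec!r} does not have 4 fields")
            if not genes:
                raise ECFormatError(f"EC group {ec} is empty")

    @property
    def ecs(self) -> list[str]:
        return sorted(self.groups)

    def __getitem__(self, ec: str) -> frozenset[str]:
        return self.groups[ec]

    def __len__(self) -> int:
        return len(self.groups)

    def disjoint_partners(self, ec: str) -> list[str]:
        mine = self.groups[ec]
        return [e for e in self.ecs if e != ec and not (self.groups[e] & mine)]


def load_ec_groups(path) -> ECGroups:
    """Read a two-column gene TAB EC table into groups.

    Partial EC numbers (any field ``-``) are dropped with a count, as are
    groups left with fewer than two genes (the diff score needs a nonempty
    own-group after removing g).
    """
    members: dict[str, set[str]] = {}
    n_partial = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ECFormatError(f"{path}:{lineno}: expected gene TAB EC")
            gene, ec = fields[0], fields[1]
            parts = ec.split(".")
            if len(parts) != 4 or any(p == "-" or not p for p in parts):
                n_partial += 1
                continue
            members.setdefault(ec, set()).add(gene)
    small = [ec for ec, genes in members.items() if len(genes) < 2]
    for ec in small:
        del members[ec]
    if small:
        logger.info("dropped %d singleton EC groups", len(small))
    if n_partial:
        logger.info("dropped %d rows with partial EC numbers", n_partial)
    if not members:
        raise ECFormatError(f"{path}: no usable EC groups")
    return ECGroups(
        groups={ec: frozenset(genes) for ec, genes in members.items()},
        n_dropped_partial=n_partial,
        n_dropped_small=len(small),
    )


def diff_score(
    g: str,
    e_i: str,
    e_j: str,
    groups: ECGroups,
    simfn: SimilarityFn,
    c_smooth: float = DEFAULT_SMOOTHING,
) -> float | None:
    """Log-ratio of inter- to intra-EC mean smoothed distance for gene g.

    Returns ``None`` when no similarity is defined against either group
    (unannotated genes are skipped, and the counts in the ratio follow the
    genes actually summed).
    """
    own = groups[e_i]
    other = groups[e_j]
    if g not in own:
        raise ValueError(f"gene {g} is not in EC group {e_i}")
    if own & other:
        raise ValueError(f"EC groups {e_i} and {e_j} share genes")
    if len(own) < 2:
        raise ValueError(f"EC group {e_i} needs >= 2 genes")
    inter = [s for gp in sorted(other) if (s := simfn(g, gp)) is not None]
    intra = [s for gs in sorted(own - {g}) if (s := simfn(g, gs)) is not None]
    if not inter or not intra:
        return None
    num = len(intra) * sum(1.0 - s + c_smooth for s in inter)
    den = len(inter) * sum(1.0 - s + c_smooth for s in intra)
    return log(num / den)


def lfc_score(
    e_i: str,
    groups: ECGroups,
    simfn: SimilarityFn,
    c_smooth: float = DEFAULT_SMOOTHING,
    cap: float = DEFAULT_CAP,
) -> float:
    """LFC(e_i): diff averaged over the group's genes, then over all
    gene-disjoint partner ECs, truncated at ``cap``.

    The normaliser counts only the partner ECs actually averaged (the
    summation's own index set); genes with no defined similarity are
    skipped within each partner mean.
    """
    partners = groups.disjoint_partners(e_i)
    if not partners:
        raise UndefinedScoreError(f"EC {e_i} has no gene-disjoint partner EC")
    partner_means = []
    for e_j in partners:
        diffs = [
            d
            for g in sorted(groups[e_i])
            if (d := diff_score(g, e_i, e_j, groups, simfn, c_smooth)) is not None
        ]
        if diffs:
            partner_means.append(sum(diffs) / len(diffs))
    if not partner_means:
        raise UndefinedScoreError(f"EC {e_i} has no scorable gene pair")
    return min(sum(partner_means) / len(partner_means), cap)


def lfc_report(
    groups: ECGroups,
    simfn: SimilarityFn,
    c_smooth: float = DEFAULT_SMOOTHING,
    cap: float = DEFAULT_CAP,
) -> pd.DataFrame:
    """Per-EC LFC table; ECs with no scorable gene are dropped with a log."""
    rows = []
    for ec in groups.ecs:
        try:
            val = lfc_score(ec, groups, simfn, c_smooth=c_smooth, cap=cap)
        except UndefinedScoreError as exc:
            logger.info("skipping EC %s: %s", ec, exc)
            continue
        rows.append(
            {
                "ec": ec,
                "lfc": val,
                "n_genes": len(groups[ec]),
                "n_partners": len(groups.disjoint_partners(ec)),
            }
        )
    return pd.DataFrame(rows, columns=["ec", "lfc", "n_genes", "n_partners"])


def quartile_summary(report: pd.DataFrame) -> pd.Series:
    """25/50/75th percentiles of the per-EC LFC scores."""
    q = report["lfc"].quantile([0.25, 0.5, 0.75])
    q.index = ["25%", "50%", "75%"]
    return q
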