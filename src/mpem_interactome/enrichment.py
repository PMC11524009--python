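"""Set-overlap enrichment statistics.

All tests are one-sided over-representation tests on a 2x2 table drawn
from a finite gene universe: the hypergeometric upper tail for plain
overlaps, Fisher's exact test for annotation collections, and
Benjamini-Hochberg step-up adjustment within each collection (never
pooled across collections).  The odds ratio is the sample odds ratio with
a Haldane-Anscombe 0.5 correction applied only when some cell is zero.

The background universe is an explicit argument everywhere: overlap
p-values are meaningless without it, and no default is assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapTable",
    "EnrichmentResult",
    "overlap_test_from_counts",
    "hypergeom_overlap",
    "fisher_enrichment",
    "bh_adjust",
    "interactome_overlap",
]


@dataclass(frozen=True)
class OverlapTable:
    """Counts behind a 2x2 overlap test: |A ∩ B| against a universe."""

    k: int
    n_a: int
    n_b: int
    n_univ: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n_a, self.n_b)):
            raise ValidationError(f"overlap k={self.k} outside [0, min(n_a, n_b)]")
        if self.n_a > self.n_univ or self.n_b > self.n_univ:
            raise ValidationError("set sizes exceed the universe")
        if self.n_univ - self.n_a - self.n_b + self.k < 0:
            raise ValidationError("2x2 table has a negative cell; universe too small")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, b, c, d) = (k, n_a - k, n_b - k, rest of universe)."""
        a = self.k
        b = self.n_a - self.k
        c = self.n_b - self.k
        d = self.n_univ - self.n_a - self.n_b + self.k
        return a, b, c, d


@dataclass
class EnrichmentResult:
    table: OverlapTable
    p: float
    odds_ratio: float
    q: float
    label: str = ""

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def sample_odds_ratio(table: OverlapTable) -> float:
    """Sample OR (a*d)/(b*c), with 0.5 added to every cell iff any is zero."""
    a, b, c, d = table.cells
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _normalize_set(genes) -> frozenset[str]:
    return frozenset(normalize_symbol(g) for g in genes)


def overlap_test_from_counts(table: OverlapTable, label: str = "") -> EnrichmentResult:
    """Hypergeometric upper-tail test on pre-computed overlap counts:
    p = P(X >= k) for X ~ Hypergeometric(n_univ, n_a, n_b)."""
    p = float(stats.hypergeom.sf(table.k - 1, table.n_univ, table.n_a, table.n_b))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(
        table=table, p=p, odds_ratio=sample_odds_ratio(table), q=p, label=label
    )


def hypergeom_overlap(set_a, set_b, universe, label: str = "") -> EnrichmentResult:
    """One-sided hypergeometric overlap test of two gene sets.

    Members outside the universe are dropped with a logged count.
    """
    universe = _normalize_set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    a, b = _normalize_set(set_a), _normalize_set(set_b)
    dropped = len(a - universe) + len(b - universe)
    if dropped:
        logger.info("dropped %d set members outside the universe", dropped)
    a &= universe
    b &= universe
    table = OverlapTable(k=len(a & b), n_a=len(a), n_b=len(b), n_univ=len(universe))
    return overlap_test_from_counts(table, label=label)


def fisher_enrichment(
    query, collection: GeneSetCollection, universe, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation test of a query against every
    set in a collection, with BH adjustment across the collection."""
    if not len(collection):
        raise ValidationError("gene-set collection is empty")
    universe = _normalize_set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    q_set = _normalize_set(query) & universe
    if not q_set:
        raise ValidationError("query is disjoint from the universe")

    results: list[EnrichmentResult] = []
    for label, members in sorted(collection.sets.items()):
        m = frozenset(members) & universe
        table = OverlapTable(
            k=len(q_set & m), n_a=len(q_set), n_b=len(m), n_univ=len(universe)
        )
        a, b_, c, d = table.cells
        _, p = stats.fisher_exact([[a, b_], [c, d]], alternative="greater")
        p = float(min(max(p, np.nextafter(0, 1)), 1.0))
        results.append(
            EnrichmentResult(table=table, p=p, odds_ratio=sample_odds_ratio(table), q=p, label=label)
        )
    qvals = bh_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = q
    return results


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def interactome_overlap(inter_a, inter_b, universe) -> dict:
    """Overlap of two interactomes' node sets, with shared seeds and
    cross-interactome edges reported separately."""
    result = hypergeom_overlap(inter_a.nodes, inter_b.nodes, universe, label="interactome_overlap")
    shared_nodes = inter_a.nodes & inter_b.nodes
    shared_seeds = sorted(inter_a.seeds & inter_b.seeds)
    cross_edges = sorted(
        {e.pair for e in inter_a.edges if e.gene_a in inter_b.nodes and e.gene_b in inter_b.nodes}
        | {e.pair for e in inter_b.edges if e.gene_a in inter_a.nodes and e.gene_b in inter_a.nodes}
    )
    return {
        "enrichment": result,
        "n_shared": len(shared_nodes),
        "shared_seeds": shared_seeds,
        "cross_edges": cross_edges,
    }
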