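"""Tissue-restricted expression classification.

Genes are classed on a gene x tissue matrix of mean TPM using fold-change
rules: *tissue-enriched* (top tissue at least ``fold`` times higher than
every other tissue), *group-enriched* (a group of 2-7 tissues all at
least ``fold`` times higher than every tissue outside the group), and
*tissue-enhanced* (top tissue at least ``fold`` times the mean over all
tissues).  Categories are mutually exclusive with precedence
enriched > group-enriched > enhanced, and every rule additionally
requires expression above ``tpm_min`` (default 1 TPM).

The specificity index of a gene for a target tissue is the mean
fractional expression decrease in the other tissues,
si = mean_t max(0, 1 - expr(t)/expr(target)); si > 0.8 is called
tissue-specific.  The fractional-decrease form is this package's explicit
definition (the index is described only qualitatively in its sources) and
is recorded in output metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, hypergeom_overlap
from .io import GeneSetCollection, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "TissueMatrix",
    "TissueSpecificityCall",
    "aggregate",
    "classify",
    "specificity_index",
    "tissue_set_enrichment",
]

CATEGORIES = ("tissue_enriched", "group_enriched", "tissue_enhanced", "not_specific")


@dataclass
class TissueMatrix:
    """Mean TPM per (gene, tissue) plus per-tissue sample counts."""

    values: pd.DataFrame  # genes x tissues
    sample_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValidationError("need at least two tissues")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate tissue names")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("TPM values must be non-negative")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class TissueSpecificityCall:
    gene: str
    category: str
    tissues: tuple[str, ...]
    fold: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.category == "group_enriched" and not (2 <= len(self.tissues) <= 7):
            raise ValidationError("group_enriched calls need 2-7 tissues")
        if self.category == "not_specific" and self.tissues:
            raise ValidationError("not_specific calls carry no tissues")


def aggregate(expr: pd.DataFrame, sample_to_tissue: dict[str, str]) -> TissueMatrix:
    """Average a gene x sample matrix into a gene x tissue matrix.

    Missing cells are ignored in the mean (counts reflect samples, not
    non-missing cells).
    """
    unmapped = [s for s in expr.columns if s not in sample_to_tissue]
    if unmapped:
        raise ValidationError(f"samples with no tissue mapping: {unmapped}")
    groups = expr.T.groupby([sample_to_tissue[s] for s in expr.columns])
    means = groups.mean().T
    counts = {t: int(n) for t, n in groups.size().items()}
    return TissueMatrix(values=means, sample_counts=counts)


def _classify_gene(
    expr: pd.Series, fold: float, tpm_min: float, group_min: int, group_max: int
) -> tuple[str, tuple[str, ...], float | None]:
    # stable descending sort, ties by tissue name, so group prefixes are reproducible
    order = sorted(expr.index, key=lambda t: (-expr[t], t))
    values = expr[order].to_numpy(dtype=float)

    top_t, top_v = order[0], values[0]
    max_rest = values[1] if len(values) > 1 else 0.0
    if top_v > tpm_min and (max_rest == 0.0 or top_v >= fold * max_rest):
        f = math.inf if max_rest == 0.0 else top_v / max_rest
        return "tissue_enriched", (top_t,), f

    for size in range(group_min, min(group_max, len(values) - 1) + 1):
        in_min = values[size - 1]
        out_max = values[size]
        if in_min > tpm_min and (out_max == 0.0 or in_min >= fold * out_max):
            f = math.inf if out_max == 0.0 else in_min / out_max
            return "group_enriched", tuple(order[:size]), f

    mean_all = float(values.mean())
    if top_v > tpm_min and (mean_all == 0.0 or top_v >= fold * mean_all):
        f = math.inf if mean_all == 0.0 else top_v / mean_all
        return "tissue_enhanced", (top_t,), f

    return "not_specific", (), None


def classify(
    matrix: TissueMatrix,
    fold: float = 5.0,
    tpm_min: float = 1.0,
    group_min: int = 2,
    group_max: int = 7,
) -> list[TissueSpecificityCall]:
    """Classify every gene in the matrix; each gene gets exactly one call."""
    if fold <= 1:
        raise ValidationError(f"fold must exceed 1, got {fold}")
    calls = []
    for gene in matrix.genes:
        cat, tissues, f = _classify_gene(
            matrix.values.loc[gene], fold, tpm_min, group_min, group_max
        )
        calls.append(TissueSpecificityCall(gene=gene, category=cat, tissues=tissues, fold=f))
    return calls


def specificity_index(matrix: TissueMatrix, gene, target_tissue: str):
    """Mean fractional expression decrease outside the target tissue.

    Returns None with a warning when the target expression is zero.
    """
    gene = normalize_symbol(gene)
    expr = matrix.values.loc[gene]
    target = float(expr[target_tissue])
    if target <= 0:
        logger.warning("specificity index undefined for %s: zero expression in %s", gene, target_tissue)
        return None
    others = expr.drop(target_tissue).to_numpy(dtype=float)
    si = float(np.mean(np.maximum(0.0, 1.0 - others / target)))
    return si


def specific_gene_sets(calls: list[TissueSpecificityCall], name: str = "tissue_specific") -> GeneSetCollection:
    """Group enriched/group-enriched/enhanced calls into per-tissue gene sets."""
    sets: dict[str, set[str]] = {}
    for call in calls:
        for t in call.tissues:
            sets.setdefault(t, set()).add(call.gene)
    return GeneSetCollection(name=name, sets={t: frozenset(g) for t, g in sets.items() if g})


def tissue_set_enrichment(
    interactome_nodes, tissue_sets: GeneSetCollection, universe
) -> list[EnrichmentResult]:
    """Hypergeometric overlap of the interactome with each tissue gene set."""
    return [
        hypergeom_overlap(interactome_nodes, members, universe, label=label)
        for label, members in sorted(tissue_sets.sets.items())
    ]
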