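"""Assembly and accounting of the seed-gene interactome.

The interactome is star-shaped around the disease-associated seed genes:
every edge touches at least one seed (seed–seed edges are allowed,
seed-free edges are rejected).  Non-seed nodes are classed as known
interactors if any incident edge has known provenance, otherwise as novel
interactors; seeds with no edges at all remain in the network as isolated
nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import EdgeRecord, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = ["Interactome", "assemble", "degree_summary", "summarize_counts", "hub_partition"]

SEED = "seed"
KNOWN_INTERACTOR = "known_interactor"
NOVEL_INTERACTOR = "novel_interactor"


@dataclass
class Interactome:
    seeds: frozenset[str]
    edges: tuple[EdgeRecord, ...]  # canonical, deduplicated, sorted
    node_class: dict[str, str]
    listed_novel: tuple[EdgeRecord, ...] = ()  # pre-dedup novel listings, for per-row accounting

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.node_class)

    def subgraph_nodes(self, provenance: str) -> frozenset[str]:
        return frozenset(
            n for e in self.edges if e.provenance == provenance for n in e.pair
        )


def assemble(
    seeds,
    known: list[EdgeRecord] | None = None,
    predicted: list[EdgeRecord] | None = None,
    threshold: float = 0.5,
) -> Interactome:
    """Build the interactome from known edges plus score-thresholded predictions.

    Predicted edges are kept only when their score is strictly greater than
    ``threshold``.  A pair present both as known and predicted resolves to
    known provenance (the event is logged).  Edges touching no seed are
    rejected with a warning.
    """
    seed_set = frozenset(normalize_symbol(s) for s in (seeds or []))
    if not seed_set:
        raise ValidationError("seed list is empty")
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")

    kept: dict[tuple[str, str], EdgeRecord] = {}
    listed_novel: list[EdgeRecord] = []
    n_no_seed = n_subthreshold = n_promoted = 0

    for rec in known or []:
        if not (rec.gene_a in seed_set or rec.gene_b in seed_set):
            n_no_seed += 1
            continue
        if rec.provenance != "known":
            rec = EdgeRecord.make(*rec.pair, provenance="known", source_tag=rec.source_tag)
        kept.setdefault(rec.pair, rec)

    for rec in predicted or []:
        if not (rec.gene_a in seed_set or rec.gene_b in seed_set):
            n_no_seed += 1
            continue
        if rec.score is not None and not rec.score > threshold:
            n_subthreshold += 1
            continue
        if rec.provenance != "novel":
            rec = EdgeRecord.make(
                *rec.pair, provenance="novel", source_tag=rec.source_tag, score=rec.score
            )
        listed_novel.append(rec)
        if rec.pair in kept:
            n_promoted += 1  # known provenance wins
            continue
        kept.setdefault(rec.pair, rec)

    if n_no_seed:
        logger.warning("rejected %d edges touching no seed gene", n_no_seed)
    if n_subthreshold:
        logger.info("excluded %d predicted pairs at score <= %g", n_subthreshold, threshold)
    if n_promoted:
        logger.info("%d predicted pairs were already known; provenance kept as known", n_promoted)

    node_class: dict[str, str] = {s: SEED for s in seed_set}
    for rec in kept.values():
        for node in rec.pair:
            if node in seed_set:
                continue
            if rec.provenance == "known":
                node_class[node] = KNOWN_INTERACTOR
            else:
                node_class.setdefault(node, NOVEL_INTERACTOR)

    edges = tuple(sorted(kept.values(), key=lambda e: e.pair))
    return Interactome(
        seeds=seed_set,
        edges=edges,
        node_class=node_class,
        listed_novel=tuple(listed_novel),
    )


def degree_summary(interactome: Interactome) -> pd.DataFrame:
    """Per-seed counts of incident known (K) and novel (N) edges,
    sorted ascending by K (ties by gene name)."""
    rows = {s: {"K": 0, "N": 0} for s in interactome.seeds}
    for e in interactome.edges:
        col = "K" if e.provenance == "known" else "N"
        for node in e.pair:
            if node in rows:
                rows[node][col] += 1
    df = pd.DataFrame(
        [(g, v["K"], v["N"]) for g, v in rows.items()], columns=["gene", "K", "N"]
    )
    return df.sort_values(["K", "gene"], kind="stable").reset_index(drop=True)


def summarize_counts(interactome: Interactome, counting: str = "unique_edges") -> dict:
    """Global interactome accounting.

    ``unique_edges`` counts canonical edges once; ``listed_pairs`` counts
    novel edges as listed per seed row (a seed–seed novel pair listed under
    both seeds counts twice).  Novel-interactor counts are reported under
    both conventions: ``n_novel_interactors`` excludes nodes that also have
    a known edge, ``n_novel_partners`` counts every non-seed node touched
    by a novel edge.
    """
    if counting not in ("unique_edges", "listed_pairs"):
        raise ValidationError(f"unknown counting convention {counting!r}")
    known_edges = [e for e in interactome.edges if e.provenance == "known"]
    novel_edges = [e for e in interactome.edges if e.provenance == "novel"]
    if counting == "listed_pairs" and interactome.listed_novel:
        n_novel = len(interactome.listed_novel)
    elif counting == "listed_pairs":
        n_novel = sum(
            2 if (e.gene_a in interactome.seeds and e.gene_b in interactome.seeds) else 1
            for e in novel_edges
        )
    else:
        n_novel = len(novel_edges)
    classes = interactome.node_class
    novel_partners = {
        n for e in novel_edges for n in e.pair if n not in interactome.seeds
    }
    seeds_with_edges = {n for e in interactome.edges for n in e.pair} & interactome.seeds
    return {
        "counting": counting,
        "n_seeds": len(interactome.seeds),
        "n_seeds_with_edges": len(seeds_with_edges),
        "n_known_edges": len(known_edges),
        "n_novel_edges": n_novel,
        "n_known_interactors": sum(1 for c in classes.values() if c == KNOWN_INTERACTOR),
        "n_novel_interactors": sum(1 for c in classes.values() if c == NOVEL_INTERACTOR),
        "n_novel_partners": len(novel_partners),
    }


def hub_partition(summary: pd.DataFrame, low_cut: int = 10, high_cut: int = 75) -> dict:
    """Split seeds into low-degree and hub sets by known-PPI count.

    Low set: seeds with K <= ``low_cut``; hub set: seeds with
    K > ``high_cut``.  Novel-PPI totals are summed over each set.
    """
    if low_cut >= high_cut:
        raise ValidationError(f"low_cut ({low_cut}) must be < high_cut ({high_cut})")
    if summary.empty:
        raise ValidationError("degree summary is empty")
    low = summary[summary["K"] <= low_cut]
    hub = summary[summary["K"] > high_cut]
    return {
        "low_genes": list(low["gene"]),
        "low_novel_sum": int(low["N"].sum()),
        "hub_genes": list(hub["gene"]),
        "hub_novel_sum": int(hub["N"].sum()),
    }
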