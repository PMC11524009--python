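"""Functional module detection: shared k-nearest-neighbour graph
construction followed by Louvain community finding, with GO-BP annotation
of the resulting modules.

Similarity between genes is the Jaccard index of their direct network
neighbourhoods; each gene's k most similar genes form its kNN set (ties
broken by gene name), and two genes are joined in the sknn graph with
weight equal to the number of kNN genes they share.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .enrichment import fisher_enrichment
from .io import GeneSetCollection, ValidationError

__all__ = ["SknnGraph", "ModulePartition", "AnnotatedModule", "build_sknn", "louvain_partition", "annotate_modules"]


@dataclass
class SknnGraph:
    graph: nx.Graph  # weighted, undirected
    k: int
    similarity: str = "neighbourhood_jaccard"

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class ModulePartition:
    assignment: dict[str, int]  # gene -> module id
    modularity_q: float
    gamma: float
    seed: int
    min_size: int

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, mid in self.assignment.items():
            out.setdefault(mid, []).append(gene)
        return {m: sorted(genes) for m, genes in out.items()}

    def large_modules(self) -> dict[int, list[str]]:
        """Modules with more than ``min_size`` genes (reporting filter)."""
        return {m: g for m, g in self.modules().items() if len(g) > self.min_size}


@dataclass
class AnnotatedModule:
    module_id: int
    genes: list[str]
    top_term: str | None
    fdr_p: float | None

    @property
    def unannotated(self) -> bool:
        return self.top_term is None


def _as_graph(obj) -> nx.Graph:
    if isinstance(obj, SknnGraph):
        return obj.graph
    if isinstance(obj, nx.Graph):
        return obj
    # an assembled interactome
    g = nx.Graph()
    g.add_nodes_from(obj.node_class)
    g.add_edges_from(e.pair for e in obj.edges)
    return g


def build_sknn(interactome, k: int = 10) -> SknnGraph:
    """Shared-kNN graph over the nodes of an interactome (or nx.Graph)."""
    g = _as_graph(interactome)
    nodes = sorted(g.nodes)
    n = len(nodes)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the node count ({n})")
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=bool)
    for u, v in g.edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = True

    counts = adj.sum(axis=1).astype(float)
    inter = (adj.astype(np.float64) @ adj.astype(np.float64).T)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(sim, -np.inf)  # a node is never its own neighbour

    # kNN membership: top-k by (similarity desc, name asc); names are the
    # sorted node order, so argsort on (-sim, index) is stable by name.
    knn = np.zeros((n, n), dtype=bool)
    order = np.argsort(-sim, axis=1, kind="stable")
    for i in range(n):
        knn[i, order[i, :k]] = True

    shared = knn.astype(np.int64) @ knn.astype(np.int64).T
    out = nx.Graph()
    out.add_nodes_from(nodes)
    ii, jj = np.nonzero(np.triu(shared, 1))
    for i, j in zip(ii, jj):
        out.add_edge(nodes[i], nodes[j], weight=int(shared[i, j]))
    return SknnGraph(graph=out, k=k)


def louvain_partition(
    graph, gamma: float = 1.0, seed: int = 0, min_size: int = 4
) -> ModulePartition:
    """Louvain community detection with a fixed seed.

    Modules of size <= ``min_size`` are retained in the partition and only
    filtered at reporting time (:meth:`ModulePartition.large_modules`).
    """
    g = _as_graph(graph)
    if g.number_of_nodes() == 0:
        raise ValidationError("graph is empty")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=gamma, seed=seed
    )
    communities = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c[0]))
    assignment = {gene: mid for mid, comm in enumerate(communities) for gene in comm}
    if g.number_of_edges() > 0:
        q = float(nx.community.modularity(g, [set(c) for c in communities], weight="weight"))
    else:
        q = 0.0
    return ModulePartition(
        assignment=assignment, modularity_q=q, gamma=gamma, seed=seed, min_size=min_size
    )


def annotate_modules(
    partition: ModulePartition,
    gobp: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> list[AnnotatedModule]:
    """Annotate each above-threshold module with its top enriched term.

    The top term minimises the BH-adjusted p within the module's own
    enrichment family; modules with no term at q < ``alpha`` are reported
    unannotated.
    """
    if not len(gobp):
        raise ValidationError("annotation collection is empty")
    out = []
    for mid, genes in sorted(partition.large_modules().items()):
        results = fisher_enrichment(genes, gobp, universe)
        best = min(results, key=lambda r: (r.q, r.p, r.label))
        if best.q < alpha:
            out.append(AnnotatedModule(module_id=mid, genes=genes, top_term=best.label, fdr_p=best.q))
        else:
            out.append(AnnotatedModule(module_id=mid, genes=genes, top_term=None, fdr_p=None))
    return out
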