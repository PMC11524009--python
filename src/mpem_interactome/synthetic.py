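"""Seeded synthetic-data generators.

Every stage of the pipeline consumes external resources (interaction
repositories, expression atlases, survival registries, drug libraries)
that cannot ship with a package.  The generators here produce inputs with
the statistical structure each stage assumes — a heavy-tailed truth
network, labelled pairs with tunable feature signal, gene sets with a
planted overlap odds ratio, tissue matrices with planted specificity
categories, survival cohorts with planted hazard genes, and drug
libraries with planted signature reversers — so the full pipeline runs
and its parameter recovery can be tested without downloads.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, ValidationError
from .ppi import AnnotationResource
from .survival import SurvivalCohort
from .tissue import TissueMatrix, TissueSpecificityCall
from .drugs import DESignature, DrugRecord

__all__ = [
    "SyntheticWorld",
    "generate_world",
    "generate_labeled_pairs",
    "generate_disease_study",
    "generate_tissue_matrix",
    "generate_survival_cohort",
    "generate_disease_signatures",
    "generate_drug_library",
]

DEFAULT_TISSUES = (
    "spleen", "thymus", "intestine", "brain", "testis", "skin",
    "lung", "heart", "oesophagus", "artery", "muscle", "liver",
)


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


@dataclass
class SyntheticWorld:
    """A self-consistent ground truth: network, annotations, coordinates
    and an expression compendium."""

    genes: list[str]
    truth: nx.Graph
    resource: AnnotationResource
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def truth_edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.truth.edges)


def generate_world(
    n_genes: int,
    seed: int,
    m: int = 3,
    n_conditions: int = 50,
    n_terms: int = 200,
    terms_per_gene: float = 5.0,
    annotation_sharing: float = 0.3,
    coexpr_rho: float = 0.6,
    n_chromosomes: int = 23,
) -> SyntheticWorld:
    """Scale-free truth network (preferential attachment, ``m`` edges per
    new node) with annotations shared preferentially along true edges and
    expression correlated for a matching of true pairs."""
    if n_genes < m + 1:
        raise ValidationError("n_genes must exceed m")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    g = nx.barabasi_albert_graph(n_genes, m, seed=int(seed))
    g = nx.relabel_nodes(g, {i: genes[i] for i in range(n_genes)})

    chrom = {x: f"chr{rng.integers(1, n_chromosomes + 1)}" for x in genes}
    pos = {x: int(rng.integers(0, 250_000_000)) for x in genes}

    def draw_terms(ns: str) -> dict[str, frozenset[str]]:
        out = {}
        for x in genes:
            k = max(1, rng.poisson(terms_per_gene))
            out[x] = frozenset(f"{ns}{t:03d}" for t in rng.choice(n_terms, size=min(k, n_terms), replace=False))
        return {k: set(v) for k, v in out.items()}  # type: ignore[return-value]

    mf, bp, loc = draw_terms("MF"), draw_terms("BP"), draw_terms("LOC")
    for u, v in g.edges:
        for terms in (mf, bp, loc):
            if rng.random() < annotation_sharing and terms[u]:
                terms[v].add(rng.choice(sorted(terms[u])))

    expr = rng.standard_normal((n_genes, n_conditions))
    gi = {x: i for i, x in enumerate(genes)}
    # correlate a matching of true pairs
    used: set[str] = set()
    edges = list(g.edges)
    rng.shuffle(edges)
    for u, v in edges:
        if u in used or v in used:
            continue
        e = rng.standard_normal(n_conditions)
        expr[gi[v]] = coexpr_rho * expr[gi[u]] + np.sqrt(1 - coexpr_rho**2) * e
        used.update((u, v))

    resource = AnnotationResource(
        localization={x: frozenset(loc[x]) for x in genes},
        mf_terms={x: frozenset(mf[x]) for x in genes},
        bp_terms={x: frozenset(bp[x]) for x in genes},
        chromosome=chrom,
        position=pos,
        expression=pd.DataFrame(expr, index=genes),
    )
    params = {
        "n_genes": n_genes, "m": m, "n_conditions": n_conditions,
        "n_terms": n_terms, "annotation_sharing": annotation_sharing,
        "coexpr_rho": coexpr_rho,
    }
    return SyntheticWorld(genes=genes, truth=g, resource=resource, params=params, seed=seed)


def generate_labeled_pairs(
    world: SyntheticWorld,
    n_pos: int,
    n_neg: int,
    signal: float,
    seed: int,
    n_conditions: int = 50,
    base_share: float = 0.1,
    share_gain: float = 0.4,
    coexpr_gain: float = 0.5,
    coexpr_sd: float = 0.2,
) -> tuple[list[tuple[tuple[str, str], int]], AnnotationResource]:
    """Labelled (pair, class) examples with feature separation ``signal``.

    Positives are a disjoint matching of truth edges, negatives disjoint
    non-edges.  Each pair's planted co-expression is drawn from
    Normal(coexpr_gain * signal, coexpr_sd) for positives and
    Normal(0, coexpr_sd) for negatives; annotation terms are shared with
    probability base_share + share_gain * signal for positives versus
    base_share for negatives.  At signal = 0 the classes are
    indistinguishable by construction.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValidationError("need n_pos > 0 and n_neg > 0")
    if not 0.0 <= signal <= 1.0:
        raise ValidationError("signal must be in [0, 1]")
    rng = np.random.default_rng(seed)

    edges = list(world.truth.edges)
    rng.shuffle(edges)
    used: set[str] = set()
    positives: list[tuple[str, str]] = []
    for u, v in edges:
        if u in used or v in used:
            continue
        positives.append(tuple(sorted((u, v))))
        used.update((u, v))
        if len(positives) == n_pos:
            break
    if len(positives) < n_pos:
        raise ValidationError(
            f"world too small for {n_pos} disjoint positive pairs (found {len(positives)})"
        )

    free = [x for x in world.genes if x not in used]
    rng.shuffle(free)
    negatives: list[tuple[str, str]] = []
    while len(negatives) >= 0 and free:
        if len(negatives) == n_neg or len(free) < 2:
            break
        u, v = free.pop(), free.pop()
        if not world.truth.has_edge(u, v):
            negatives.append(tuple(sorted((u, v))))
    if len(negatives) < n_neg:
        raise ValidationError("world too small for the requested negative pairs")

    involved = sorted({x for p in positives + negatives for x in p})
    expr = pd.DataFrame(
        rng.standard_normal((len(involved), n_conditions)), index=involved
    )
    # fresh annotation draws: the world's term sets share along truth edges,
    # which would leak class signal at signal = 0
    n_terms = int(world.params.get("n_terms", 200))
    rate = float(world.params.get("terms_per_gene", 5.0)) if "terms_per_gene" in world.params else 5.0

    def fresh_terms(ns: str) -> dict[str, set[str]]:
        out = {}
        for x in involved:
            k = max(1, rng.poisson(rate))
            out[x] = {f"{ns}{t:03d}" for t in rng.choice(n_terms, size=min(k, n_terms), replace=False)}
        return out

    mf, bp, loc = fresh_terms("MF"), fresh_terms("BP"), fresh_terms("LOC")

    def plant(pairs: list[tuple[str, str]], mean_rho: float, p_share: float) -> None:
        for a, b in pairs:
            r = float(np.clip(rng.normal(mean_rho, coexpr_sd), -0.9, 0.9))
            e = rng.standard_normal(n_conditions)
            expr.loc[b] = r * expr.loc[a].to_numpy() + np.sqrt(1 - r**2) * e
            for terms in (mf, bp, loc):
                for t in sorted(terms[a]):
                    if rng.random() < p_share:
                        terms[b].add(t)

    plant(positives, coexpr_gain * signal, base_share + share_gain * signal)
    plant(negatives, 0.0, base_share)

    resource = AnnotationResource(
        localization={x: frozenset(loc[x]) for x in involved},
        mf_terms={x: frozenset(mf[x]) for x in involved},
        bp_terms={x: frozenset(bp[x]) for x in involved},
        chromosome=dict(world.resource.chromosome),
        position=dict(world.resource.position),
        expression=expr,
    )
    labeled = [(p, 1) for p in positives] + [(p, 0) for p in negatives]
    return labeled, resource


def generate_disease_study(
    interactome_nodes,
    planted_or: float,
    set_size: int,
    universe_size: int,
    seed: int,
    name: str = "synthetic_de_study",
) -> GeneSetCollection:
    """A differential-expression gene set whose overlap with the
    interactome has expected odds ratio ``planted_or``.

    The overlap count is drawn from Fisher's noncentral hypergeometric
    distribution with odds parameter ``planted_or``.
    """
    nodes = sorted(set(interactome_nodes))
    if set_size > universe_size:
        raise ValidationError("set_size exceeds universe_size")
    if len(nodes) >= universe_size:
        raise ValidationError("universe must exceed the interactome")
    if planted_or <= 0:
        raise ValidationError("planted_or must be positive")
    rng = np.random.default_rng(seed)
    filler = _gene_names(universe_size - len(nodes), prefix="U")
    universe = nodes + filler
    k = int(
        stats.nchypergeom_fisher.rvs(
            universe_size, len(nodes), set_size, planted_or, random_state=rng
        )
    )
    members = list(rng.choice(nodes, size=k, replace=False)) + list(
        rng.choice(filler, size=set_size - k, replace=False)
    )
    return GeneSetCollection(
        name=name,
        sets={"DEG": frozenset(members)},
        universe=frozenset(universe),
    )


def generate_tissue_matrix(
    n_genes: int,
    tissues=DEFAULT_TISSUES,
    planted: dict[str, TissueSpecificityCall] | None = None,
    baseline_tpm: float = 5.0,
    noise_cv: float = 0.1,
    seed: int = 0,
    enriched_fold: float = 8.0,
    enhanced_fold: float = 16.0,
    enhanced_decoy_fold: float = 4.5,
) -> TissueMatrix:
    """Gene x tissue TPM matrix with planted specificity categories.

    Non-planted genes sit at ``baseline_tpm`` in every tissue.  Planted
    enriched/group-enriched genes are raised ``enriched_fold`` above
    baseline in their tissue(s); planted enhanced genes are raised
    ``enhanced_fold`` in the target tissue with one decoy tissue at
    ``enhanced_decoy_fold`` (high enough to block the enriched rule, low
    enough to keep the gene above five times the all-tissue mean).
    Multiplicative Gaussian noise with coefficient of variation
    ``noise_cv`` is applied everywhere.
    """
    tissues = list(tissues)
    planted = planted or {}
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes, prefix="T")
    values = np.full((n_genes, len(tissues)), baseline_tpm, dtype=float)
    gi = {g: i for i, g in enumerate(genes)}
    ti = {t: i for i, t in enumerate(tissues)}

    for gene, call in planted.items():
        if gene not in gi:
            raise ValidationError(f"planted gene {gene!r} not among generated genes")
        if call.category == "tissue_enriched":
            values[gi[gene], ti[call.tissues[0]]] = enriched_fold * baseline_tpm
        elif call.category == "group_enriched":
            if not 2 <= len(call.tissues) <= 7:
                raise ValidationError("planted group size must be 2-7")
            for t in call.tissues:
                values[gi[gene], ti[t]] = enriched_fold * baseline_tpm
        elif call.category == "tissue_enhanced":
            target = ti[call.tissues[0]]
            values[gi[gene], target] = enhanced_fold * baseline_tpm
            decoy = (target + 1) % len(tissues)
            values[gi[gene], decoy] = enhanced_decoy_fold * baseline_tpm
        else:
            raise ValidationError(f"cannot plant category {call.category!r}")

    if noise_cv > 0:
        values = values * (1 + noise_cv * rng.standard_normal(values.shape))
        values = np.clip(values, 0.0, None)
    df = pd.DataFrame(values, index=genes, columns=tissues)
    return TissueMatrix(values=df, sample_counts={t: 1 for t in tissues})


def generate_survival_cohort(
    n_patients: int,
    genes,
    planted_hr: dict[str, float] | None = None,
    censor_rate: float = 0.2,
    seed: int = 0,
    base_hazard: float = 0.02,
) -> SurvivalCohort:
    """Survival cohort with exponential event times and planted hazard genes.

    Each gene's expression is standard normal; patients above the median
    of a planted gene have their hazard multiplied by that gene's hazard
    ratio.  Censoring is by an independent exponential time whose rate
    gives an expected censoring fraction of ``censor_rate``
    (``censor_rate=1`` censors everyone).
    """
    genes = list(genes)
    planted_hr = planted_hr or {}
    if not set(planted_hr) <= set(genes):
        raise ValidationError("planted genes must be among the cohort genes")
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(
        rng.standard_normal((n_patients, len(genes))), columns=genes
    )
    log_rate = np.full(n_patients, np.log(base_hazard))
    for gene, hr in planted_hr.items():
        if hr <= 0:
            raise ValidationError("hazard ratios must be positive")
        x = expr[gene].to_numpy()
        high = x > np.median(x)
        log_rate = log_rate + np.log(hr) * high
    t_event = rng.exponential(1.0 / np.exp(log_rate))

    if censor_rate >= 1.0:
        time, event = rng.exponential(1.0 / base_hazard, size=n_patients), np.zeros(n_patients, dtype=int)
    elif censor_rate <= 0.0:
        time, event = t_event, np.ones(n_patients, dtype=int)
    else:
        lam_c = base_hazard * censor_rate / (1 - censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n_patients)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-9)
    return SurvivalCohort(time=time, event=event, expression=expr)


def generate_disease_signatures(
    n_signatures: int,
    n_genes: int,
    seed: int,
    latent_weight: float = 0.8,
) -> list[DESignature]:
    """Disease differential-expression contrasts sharing a latent profile.

    Each signature is latent_weight * z + sqrt(1 - latent_weight^2) * eps
    over a common latent log-fold-change profile z, so the contrasts are
    positively correlated (heterogeneous datasets of one disease)."""
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes, prefix="S")
    z = rng.standard_normal(n_genes)
    sigs = []
    for i in range(n_signatures):
        eps = rng.standard_normal(n_genes)
        lfc = latent_weight * z + np.sqrt(1 - latent_weight**2) * eps
        sigs.append(
            DESignature(
                name=f"disease_{i + 1}",
                lfc=dict(zip(genes, lfc)),
                contrast=f"synthetic disease contrast {i + 1}",
            )
        )
    return sigs


def generate_drug_library(
    n_drugs: int,
    disease_sigs: list[DESignature],
    planted_reversers: list[str],
    noise_sd: float,
    seed: int,
    interactome_nodes=(),
    targets_per_drug: int = 3,
) -> list[DrugRecord]:
    """Drug records with signatures and targets; planted reversers carry
    the negated mean disease signature plus Gaussian noise and always
    target at least one interactome node."""
    if n_drugs == 0:
        return []
    if not disease_sigs:
        raise ValidationError("need at least one disease signature")
    rng = np.random.default_rng(seed)
    genes = sorted(set.union(*(set(s.lfc) for s in disease_sigs)))
    mean_lfc = np.mean([[s.lfc.get(g, 0.0) for g in genes] for s in disease_sigs], axis=0)
    ids = [f"D{i:03d}" for i in range(1, n_drugs + 1)]
    unknown = set(planted_reversers) - set(ids)
    if unknown:
        raise ValidationError(f"planted reversers not in drug ids: {sorted(unknown)}")
    nodes = sorted(set(interactome_nodes))
    target_pool = nodes + _gene_names(200, prefix="X")

    drugs = []
    for did in ids:
        if did in planted_reversers:
            lfc = -mean_lfc + noise_sd * rng.standard_normal(len(genes))
            targets = set(rng.choice(nodes or target_pool, size=1))
            extra = rng.choice(target_pool, size=max(0, targets_per_drug - 1), replace=False)
            targets |= set(extra)
        else:
            lfc = rng.standard_normal(len(genes))
            targets = set(rng.choice(target_pool, size=targets_per_drug, replace=False))
        sig = DESignature(name=did, lfc=dict(zip(genes, lfc)), contrast="drug vs vehicle")
        drugs.append(
            DrugRecord(drug_id=did, name=f"drug-{did[1:]}", targets=frozenset(targets), signature=sig)
        )
    return drugs
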