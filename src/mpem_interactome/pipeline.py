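"""End-to-end pipeline orchestration from a single flat config file.

``run_all`` executes the six analysis stages in dependency order —
assemble, overlap enrichment, tissue specificity, functional modules,
prognostic screening, drug repurposing — writing per-stage TSV outputs
and a versioned ``report.json``.  A stage is skipped on re-run when its
outputs already exist and the hash of its configuration slice is
unchanged; any stage failure is recorded and downstream stages are
skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drugs as drugs_mod
from . import enrichment as enr
from . import interactome as inter
from . import network_modules as nm
from . import survival as surv
from . import synthetic as syn
from . import tissue as tis
from .io import (
    GeneSetCollection,
    ValidationError,
    read_edge_list,
    read_edge_list_tsv,
    read_gmt,
    read_matrix,
    read_seed_genes,
    write_edge_list,
    write_gmt,
)
from .tissue import TissueSpecificityCall

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

__all__ = ["PipelineConfig", "run_all", "write_synthetic_inputs"]


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; every published cutoff is a default."""

    outdir: str
    seeds_file: str
    known_edges_file: str
    gene_sets_file: str
    universe_file: str
    expression_file: str
    sample_map_file: str
    gobp_file: str
    survival_file: str
    drug_targets_file: str
    drug_sigs_dir: str
    disease_sigs_dir: str
    predicted_file: str | None = None
    prediction_threshold: float = 0.5
    enrichment_alpha: float = 0.05
    tissue_fold: float = 5.0
    tpm_min: float = 1.0
    sknn_k: int = 10
    louvain_gamma: float = 1.0
    louvain_seed: int = 42
    logrank_threshold: float = 0.001
    drug_alpha: float = 0.05
    min_datasets: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if f.name.endswith(("_file", "_dir")) and f.name != "predicted_file":
                p = getattr(self, f.name)
                if not Path(p).exists():
                    raise ValidationError(f"{f.name}: {p} does not exist")
        if self.predicted_file and not Path(self.predicted_file).exists():
            raise ValidationError(f"predicted_file: {self.predicted_file} does not exist")
        if not 0 <= self.prediction_threshold <= 1:
            raise ValidationError("prediction_threshold outside [0, 1]")
        if not 0 < self.enrichment_alpha < 1 or not 0 < self.logrank_threshold < 1:
            raise ValidationError("significance thresholds must lie in (0, 1)")

    def stage_slice(self, keys: tuple[str, ...]) -> dict:
        return {k: getattr(self, k) for k in keys}


_STAGE_KEYS = {
    "assemble": ("seeds_file", "known_edges_file", "predicted_file", "prediction_threshold"),
    "enrichment": ("gene_sets_file", "universe_file", "enrichment_alpha"),
    "tissue": ("expression_file", "sample_map_file", "tissue_fold", "tpm_min"),
    "modules": ("gobp_file", "sknn_k", "louvain_gamma", "louvain_seed"),
    "survival": ("survival_file", "logrank_threshold"),
    "drugs": ("drug_targets_file", "drug_sigs_dir", "disease_sigs_dir", "drug_alpha", "min_datasets"),
}


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _read_scored_pairs(path):
    df = pd.read_csv(path, sep="\t", comment="#")
    from .io import EdgeRecord

    return [
        EdgeRecord.make(r.gene_a, r.gene_b, provenance="novel", source_tag="predicted", score=float(r.score))
        for r in df.itertuples(index=False)
    ]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / "report.json"
    previous = {}
    if report_path.exists():
        try:
            previous = json.loads(report_path.read_text()).get("stages", {})
        except json.JSONDecodeError:
            previous = {}

    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "stages": {}}
    state: dict = {}
    failed = False

    def run_stage(name, fn, outputs):
        nonlocal failed
        cfg = config.stage_slice(_STAGE_KEYS[name])
        h = _hash(cfg)
        block = {"params": cfg, "config_hash": h, "outputs": [str(outdir / o) for o in outputs]}
        if failed:
            block["status"] = "skipped_upstream_failure"
            report["stages"][name] = block
            return
        prev = previous.get(name, {})
        cached = (
            prev.get("config_hash") == h
            and prev.get("status") in ("ok", "cached")
            and all(Path(p).exists() for p in prev.get("outputs", []))
        )
        try:
            if cached and name == "assemble":
                # reload the interactome so downstream stages can run
                edges = read_edge_list_tsv(outdir / "interactome_edges.tsv")
                nodes = pd.read_csv(outdir / "interactome_nodes.tsv", sep="\t")
                seeds = frozenset(nodes.loc[nodes["node_class"] == "seed", "gene"])
                state["interactome"] = inter.Interactome(
                    seeds=seeds,
                    edges=tuple(edges),
                    node_class=dict(zip(nodes["gene"], nodes["node_class"])),
                )
                block["summary"] = prev.get("summary")
                block["status"] = "cached"
            elif cached:
                block["summary"] = prev.get("summary")
                block["status"] = "cached"
            else:
                block["summary"] = fn(cfg)
                block["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - report and halt downstream
            logger.error("stage %s failed: %s", name, exc)
            block["status"] = "failed"
            block["error"] = f"{type(exc).__name__}: {exc}"
            failed = True
        report["stages"][name] = block

    def stage_assemble(cfg):
        seeds = read_seed_genes(config.seeds_file, column="gene")
        known = read_edge_list(config.known_edges_file, dialect="simple2col", provenance="known")
        predicted = _read_scored_pairs(config.predicted_file) if config.predicted_file else []
        net = inter.assemble(seeds, known, predicted, threshold=config.prediction_threshold)
        state["interactome"] = net
        write_edge_list(outdir / "interactome_edges.tsv", net.edges)
        pd.DataFrame(
            sorted(net.node_class.items()), columns=["gene", "node_class"]
        ).to_csv(outdir / "interactome_nodes.tsv", sep="\t", index=False)
        counts = inter.summarize_counts(net, counting="unique_edges")
        (outdir / "interactome_counts.json").write_text(json.dumps(counts, indent=1))
        return counts

    def stage_enrichment(cfg):
        net = state["interactome"]
        sets = read_gmt(config.gene_sets_file)
        universe = read_seed_genes(config.universe_file, column="gene")
        results = enr.fisher_enrichment(net.nodes, sets, universe, alpha=config.enrichment_alpha)
        _write_enrichment(outdir / "overlap_enrichment.tsv", results)
        return {"n_sets": len(results), "n_significant": sum(r.significant for r in results)}

    def stage_tissue(cfg):
        expr = read_matrix(config.expression_file, orientation="genes_by_rows")
        smap = pd.read_csv(config.sample_map_file, sep="\t", comment="#")
        mapping = dict(zip(smap["sample"], smap["tissue"]))
        matrix = tis.aggregate(expr, mapping)
        calls = tis.classify(matrix, fold=config.tissue_fold, tpm_min=config.tpm_min)
        rows = [
            (c.gene, c.category, ",".join(c.tissues), "" if c.fold is None else f"{c.fold:.4g}")
            for c in calls
        ]
        pd.DataFrame(rows, columns=["gene", "category", "tissues", "fold"]).to_csv(
            outdir / "tissue_calls.tsv", sep="\t", index=False
        )
        net = state["interactome"]
        tissue_sets = tis.specific_gene_sets(calls)
        summary = {"n_genes": len(calls), "n_specific": sum(c.category != "not_specific" for c in calls)}
        if len(tissue_sets):
            results = tis.tissue_set_enrichment(net.nodes, tissue_sets, matrix.genes)
            _write_enrichment(outdir / "tissue_enrichment.tsv", results)
            summary["n_tissue_sets"] = len(tissue_sets)
        return summary

    def stage_modules(cfg):
        net = state["interactome"]
        sknn = nm.build_sknn(net, k=config.sknn_k)
        partition = nm.louvain_partition(
            sknn, gamma=config.louvain_gamma, seed=config.louvain_seed
        )
        gobp = read_gmt(config.gobp_file)
        annotated = nm.annotate_modules(partition, gobp, net.nodes)
        rows = [
            (m.module_id, len(m.genes), m.top_term or "unannotated",
             "" if m.fdr_p is None else f"{m.fdr_p:.3g}", ",".join(m.genes))
            for m in annotated
        ]
        pd.DataFrame(rows, columns=["module", "size", "top_term", "fdr_p", "genes"]).to_csv(
            outdir / "modules.tsv", sep="\t", index=False
        )
        return {
            "n_modules": len(partition.modules()),
            "n_reported": len(annotated),
            "modularity_q": partition.modularity_q,
        }

    def stage_survival(cfg):
        df = pd.read_csv(config.survival_file, sep="\t", comment="#")
        expr = df.drop(columns=["time", "event"])
        cohort = surv.SurvivalCohort(
            time=df["time"].to_numpy(), event=df["event"].to_numpy(), expression=expr
        )
        calls = surv.prognostic_screen(cohort, p_threshold=config.logrank_threshold)
        rows = [
            (c.gene, "" if c.chi2 is None else f"{c.chi2:.4g}",
             "" if c.p is None else f"{c.p:.3g}", c.direction)
            for c in calls
        ]
        pd.DataFrame(rows, columns=["gene", "chi2", "p", "direction"]).to_csv(
            outdir / "prognostic.tsv", sep="\t", index=False
        )
        return {
            "n_genes": len(calls),
            "n_prognostic": sum(c.direction != "none" for c in calls),
        }

    def stage_drugs(cfg):
        net = state["interactome"]
        drug_records = drugs_mod.read_drug_targets(config.drug_targets_file)
        sig_by_drug = {}
        for p in sorted(Path(config.drug_sigs_dir).glob("*.tsv")):
            sig_by_drug[p.stem] = drugs_mod.read_signature(p)
        for d in drug_records:
            d.signature = sig_by_drug.get(d.drug_id)
        disease_sigs = [
            drugs_mod.read_signature(p) for p in sorted(Path(config.disease_sigs_dir).glob("*.tsv"))
        ]
        candidates = drugs_mod.shortlist(
            drug_records, disease_sigs, net,
            alpha=config.drug_alpha, min_datasets=config.min_datasets,
        )
        rows = [
            (c.rank, c.drug_id, c.name, c.group, c.n_negative, f"{c.mean_rho:.4g}",
             ",".join(sorted(c.targeted_nodes)))
            for c in candidates
        ]
        pd.DataFrame(
            rows, columns=["rank", "drug_id", "name", "group", "n_negative", "mean_rho", "targets_in_interactome"],
        ).to_csv(outdir / "drug_candidates.tsv", sep="\t", index=False)
        return {
            "n_candidates": len(candidates),
            "n_multi_dataset": sum(c.group == "multi_dataset" for c in candidates),
            "n_single_dataset": sum(c.group == "single_dataset" for c in candidates),
            "target_summary": drugs_mod.drug_target_summary(drug_records, net),
        }

    run_stage("assemble", stage_assemble, ["interactome_edges.tsv", "interactome_nodes.tsv", "interactome_counts.json"])
    run_stage("enrichment", stage_enrichment, ["overlap_enrichment.tsv"])
    run_stage("tissue", stage_tissue, ["tissue_calls.tsv"])
    run_stage("modules", stage_modules, ["modules.tsv"])
    run_stage("survival", stage_survival, ["prognostic.tsv"])
    run_stage("drugs", stage_drugs, ["drug_candidates.tsv"])

    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _write_enrichment(path, results) -> None:
    rows = [
        (r.label, r.table.k, r.table.n_a, r.table.n_b, r.table.n_univ,
         f"{r.p:.6g}", f"{r.odds_ratio:.6g}", f"{r.q:.6g}", r.significant)
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["label", "k", "n_a", "n_b", "n_univ", "p", "odds_ratio", "q", "significant"],
    ).to_csv(path, sep="\t", index=False)


def write_synthetic_inputs(outdir, seed: int = 42, n_genes: int = 400) -> PipelineConfig:
    """Generate a complete, mutually consistent set of synthetic input
    files plus a ready-to-run config; returns the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    world = syn.generate_world(n_genes=n_genes, seed=seed)

    # seeds: a mix of hubs and low-degree genes
    degrees = sorted(world.truth.degree, key=lambda kv: -kv[1])
    seeds = sorted([g for g, _ in degrees[:10]] + [g for g, _ in degrees[-10:]])
    pd.DataFrame({"gene": seeds}).to_csv(outdir / "seeds.tsv", sep="\t", index=False)

    seed_set = set(seeds)
    known = [e for e in world.truth_edges if e[0] in seed_set or e[1] in seed_set]
    with open(outdir / "known_edges.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in known:
            fh.write(f"{a}\t{b}\n")

    # predicted pairs: random seed-anchored non-edges with scores
    non_seed = [g for g in world.genes if g not in seed_set]
    with open(outdir / "predicted_pairs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for s in seeds[:10]:
            partners = rng.choice(non_seed, size=8, replace=False)
            for p in partners:
                if not world.truth.has_edge(s, p):
                    fh.write(f"{s}\t{p}\t{rng.uniform(0.3, 1.0):.3f}\n")

    node_estimate = {n for e in known for n in e} | seed_set
    study = syn.generate_disease_study(
        node_estimate, planted_or=2.0, set_size=min(150, n_genes), universe_size=4 * n_genes, seed=seed + 1
    )
    write_gmt(outdir / "disease_sets.gmt", study)
    pd.DataFrame({"gene": sorted(study.universe)}).to_csv(outdir / "universe.tsv", sep="\t", index=False)

    # tissue expression: 2 samples per tissue around a planted matrix
    planted = {
        "T0001": TissueSpecificityCall("T0001", "tissue_enriched", ("spleen",)),
        "T0002": TissueSpecificityCall("T0002", "group_enriched", ("spleen", "thymus")),
    }
    matrix = syn.generate_tissue_matrix(
        n_genes=60, planted={k: v for k, v in planted.items()}, noise_cv=0.05, seed=seed + 2
    )
    samples = {}
    mapping_rows = []
    for t in matrix.tissues:
        for rep in (1, 2):
            sname = f"{t}_s{rep}"
            noise = 1 + 0.05 * rng.standard_normal(len(matrix.genes))
            samples[sname] = np.clip(matrix.values[t].to_numpy() * noise, 0, None)
            mapping_rows.append((sname, t))
    expr = pd.DataFrame(samples, index=matrix.genes)
    expr.index.name = "gene"
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    pd.DataFrame(mapping_rows, columns=["sample", "tissue"]).to_csv(
        outdir / "sample_map.tsv", sep="\t", index=False
    )

    # GO-BP-like sets from the world's BP annotations (term -> genes)
    term_sets: dict[str, set[str]] = {}
    for gene, terms in world.resource.bp_terms.items():
        for t in terms:
            term_sets.setdefault(t, set()).add(gene)
    big = {t: frozenset(g) for t, g in term_sets.items() if len(g) >= 5}
    write_gmt(outdir / "gobp.gmt", GeneSetCollection(name="gobp", sets=big))

    # survival cohort over a few interactome genes
    surv_genes = seeds[:8]
    cohort = syn.generate_survival_cohort(
        n_patients=120, genes=surv_genes, planted_hr={surv_genes[0]: 3.0}, seed=seed + 3
    )
    sdf = cohort.expression.copy()
    sdf.insert(0, "event", cohort.event)
    sdf.insert(0, "time", cohort.time)
    sdf.to_csv(outdir / "survival.tsv", sep="\t", index=False)

    # drugs
    disease_sigs = syn.generate_disease_signatures(5, n_genes=300, seed=seed + 4)
    library = syn.generate_drug_library(
        30, disease_sigs, planted_reversers=["D001"], noise_sd=0.3, seed=seed + 5,
        interactome_nodes=node_estimate,
    )
    (outdir / "drug_sigs").mkdir(exist_ok=True)
    (outdir / "disease_sigs").mkdir(exist_ok=True)
    with open(outdir / "drug_targets.tsv", "w") as fh:
        fh.write("drug_id\tname\ttarget_symbol\n")
        for d in library:
            for t in sorted(d.targets):
                fh.write(f"{d.drug_id}\t{d.name}\t{t}\n")
            drugs_mod.write_signature(outdir / "drug_sigs" / f"{d.drug_id}.tsv", d.signature)
    for s in disease_sigs:
        drugs_mod.write_signature(outdir / "disease_sigs" / f"{s.name}.tsv", s)

    config = PipelineConfig(
        outdir=str(outdir / "results"),
        seeds_file=str(outdir / "seeds.tsv"),
        known_edges_file=str(outdir / "known_edges.tsv"),
        predicted_file=str(outdir / "predicted_pairs.tsv"),
        gene_sets_file=str(outdir / "disease_sets.gmt"),
        universe_file=str(outdir / "universe.tsv"),
        expression_file=str(outdir / "expression.tsv"),
        sample_map_file=str(outdir / "sample_map.tsv"),
        gobp_file=str(outdir / "gobp.gmt"),
        survival_file=str(outdir / "survival.tsv"),
        drug_targets_file=str(outdir / "drug_targets.tsv"),
        drug_sigs_dir=str(outdir / "drug_sigs"),
        disease_sigs_dir=str(outdir / "disease_sigs"),
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)
    return config
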