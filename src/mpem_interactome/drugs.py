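"""Transcriptome-reversal drug repurposing.

A drug is shortlisted when (i) its induced differential-expression
signature correlates negatively (Spearman rho < 0 at p <= alpha over at
least ``min_shared`` shared genes) with at least ``min_datasets`` disease
signatures, and (ii) it targets at least one protein in the assembled
interactome.  Candidates are ranked by (number of reversed datasets
descending, mean rho ascending) and stratified into multi-dataset and
single-dataset groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "DESignature",
    "DrugRecord",
    "RepurposingCandidate",
    "signature_correlation",
    "shortlist",
    "drug_target_summary",
]


@dataclass
class DESignature:
    """A differential-expression contrast: gene -> log2 fold change."""

    name: str
    lfc: dict[str, float]
    pvalues: dict[str, float] | None = None
    contrast: str = ""

    def __post_init__(self) -> None:
        self.lfc = {normalize_symbol(g): float(v) for g, v in self.lfc.items()}
        if len(self.lfc) < 10:
            raise ValidationError(f"signature {self.name!r} needs >= 10 genes")
        if not all(np.isfinite(list(self.lfc.values()))):
            raise ValidationError(f"signature {self.name!r} has non-finite values")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.lfc)


@dataclass
class DrugRecord:
    drug_id: str
    name: str
    targets: frozenset[str]
    signature: DESignature | None = None

    def __post_init__(self) -> None:
        self.targets = frozenset(normalize_symbol(t) for t in self.targets)


@dataclass
class RepurposingCandidate:
    drug_id: str
    name: str
    n_negative: int
    correlations: dict[str, tuple[float, float, int]]  # dataset -> (rho, p, n_shared)
    targeted_nodes: dict[str, str]  # node -> node class
    rank: int = 0

    @property
    def mean_rho(self) -> float:
        qualifying = [r for r, _, _ in self.correlations.values()]
        return float(np.mean(qualifying)) if qualifying else float("nan")

    @property
    def group(self) -> str:
        return "multi_dataset" if self.n_negative >= 2 else "single_dataset"


def signature_correlation(
    drug_sig: DESignature, disease_sig: DESignature, min_shared: int = 10
):
    """Spearman correlation of two signatures over their shared genes.

    Returns (rho, p, n_shared), or None with a warning when fewer than
    ``min_shared`` genes are shared.
    """
    shared = sorted(drug_sig.genes & disease_sig.genes)
    if len(shared) < min_shared:
        logger.warning(
            "signatures %s / %s share only %d genes (< %d); no correlation computed",
            drug_sig.name, disease_sig.name, len(shared), min_shared,
        )
        return None
    x = [drug_sig.lfc[g] for g in shared]
    y = [disease_sig.lfc[g] for g in shared]
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), len(shared)


def shortlist(
    drugs: list[DrugRecord],
    disease_sigs: list[DESignature],
    interactome,
    alpha: float = 0.05,
    min_datasets: int = 1,
    min_shared: int = 10,
    adjust: bool = False,
) -> list[RepurposingCandidate]:
    """Apply the two repurposing gates and rank the surviving drugs.

    With ``adjust=True`` the per-dataset correlation p-values are BH
    adjusted across drugs within each dataset before thresholding.
    """
    if not disease_sigs:
        raise ValidationError("need at least one disease signature")
    nodes = interactome.node_class

    # correlation matrix: drug x dataset
    corr: dict[str, dict[str, tuple[float, float, int]]] = {}
    for drug in drugs:
        if drug.signature is None:
            logger.info("drug %s has no signature; excluded", drug.drug_id)
            continue
        corr[drug.drug_id] = {}
        for sig in disease_sigs:
            res = signature_correlation(drug.signature, sig, min_shared=min_shared)
            if res is not None:
                corr[drug.drug_id][sig.name] = res

    if adjust:
        from .enrichment import bh_adjust

        for sig in disease_sigs:
            ids = [d for d in corr if sig.name in corr[d]]
            if not ids:
                continue
            qs = bh_adjust([max(corr[d][sig.name][1], np.nextafter(0, 1)) for d in ids])
            for d, q in zip(ids, qs):
                rho, _, n = corr[d][sig.name]
                corr[d][sig.name] = (rho, q, n)

    candidates = []
    for drug in drugs:
        if drug.drug_id not in corr:
            continue
        negative = {
            ds: (rho, p, n)
            for ds, (rho, p, n) in corr[drug.drug_id].items()
            if rho < 0 and p <= alpha
        }
        targeted = {t: nodes[t] for t in drug.targets if t in nodes}
        if len(negative) >= min_datasets and targeted:
            candidates.append(
                RepurposingCandidate(
                    drug_id=drug.drug_id,
                    name=drug.name,
                    n_negative=len(negative),
                    correlations=negative,
                    targeted_nodes=targeted,
                )
            )
    candidates.sort(key=lambda c: (-c.n_negative, c.mean_rho, c.drug_id))
    for i, c in enumerate(candidates, start=1):
        c.rank = i
    return candidates


def read_drug_targets(path) -> list[DrugRecord]:
    """Read a drug-target TSV (columns: drug_id, name, target_symbol)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"drug_id", "name", "target_symbol"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: drug-target TSV needs columns {sorted(need)}")
    out = []
    for (did, name), grp in df.groupby(["drug_id", "name"], sort=True):
        out.append(
            DrugRecord(drug_id=did, name=name, targets=frozenset(grp["target_symbol"]))
        )
    return out


def read_signature(path, name: str | None = None, contrast: str = "") -> DESignature:
    """Read a signature TSV (columns: gene, log2fc[, p])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "log2fc"} <= set(df.columns):
        raise ValidationError(f"{path}: signature TSV needs columns gene, log2fc")
    lfc = dict(zip(df["gene"], df["log2fc"].astype(float)))
    pvals = dict(zip(df["gene"], df["p"].astype(float))) if "p" in df.columns else None
    from pathlib import Path as _P

    return DESignature(name=name or _P(path).stem, lfc=lfc, pvalues=pvals, contrast=contrast)


def write_signature(path, sig: DESignature) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlog2fc\n")
        for g in sorted(sig.lfc):
            fh.write(f"{g}\t{sig.lfc[g]:.10g}\n")


def drug_target_summary(drugs: list[DrugRecord], interactome) -> dict:
    """How many drugs hit the interactome, and which node classes they hit."""
    nodes = interactome.node_class
    targeted: set[str] = set()
    n_targeting = 0
    for drug in drugs:
        hit = drug.targets & set(nodes)
        if hit:
            n_targeting += 1
            targeted |= hit
    by_class: dict[str, int] = {}
    for t in targeted:
        by_class[nodes[t]] = by_class.get(nodes[t], 0) + 1
    return {
        "n_drugs_targeting": n_targeting,
        "n_targeted_nodes": len(targeted),
        "n_targeted_by_class": by_class,
    }
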