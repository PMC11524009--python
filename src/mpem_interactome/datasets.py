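"""Bundled curated tables for the malignant peritoneal mesothelioma (MPeM)
seed-gene interactome.

Two small TSV files ship with the package:

``seed_gene_studies.tsv``
    One row per (study, gene): the MPeM-associated genes reported by nine
    genetic studies (mutation, copy-number, rearrangement and expression
    evidence).  The union is the 59-gene seed list.

``novel_ppi_table.tsv``
    One row per seed gene with its published count of known PPIs
    (``n_known``), count of predicted novel PPIs (``n_novel``), and the
    comma-separated list of predicted novel interactors.  The MRE11 row
    prints n_novel = 8 but lists only 7 usable partner symbols (one token
    in the source table is a dash); the table keeps the printed count and
    the 7 partners, and :func:`load_novel_ppi_table` exposes the
    discrepancy rather than hiding it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import EdgeRecord

__all__ = [
    "load_seed_gene_studies",
    "load_seed_genes",
    "load_novel_ppi_table",
    "novel_edge_records",
    "published_degree_table",
]


def _data_path(name: str):
    return resources.files("mpem_interactome.data") / name


def load_seed_gene_studies() -> pd.DataFrame:
    """Per-study seed-gene listings (columns: study, gene)."""
    with resources.as_file(_data_path("seed_gene_studies.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_seed_genes() -> list[str]:
    """The union of seed genes over all studies, order-preserving (59 genes)."""
    df = load_seed_gene_studies()
    seen: dict[str, None] = {}
    for g in df["gene"]:
        seen.setdefault(g, None)
    return list(seen)


def load_novel_ppi_table() -> pd.DataFrame:
    """Per-seed known/novel PPI accounting.

    Columns: gene, n_known, n_novel, novel_partners (comma-joined),
    n_listed (count of usable partner symbols).  ``n_listed`` differs from
    ``n_novel`` only for MRE11 (7 vs 8).
    """
    with resources.as_file(_data_path("novel_ppi_table.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", keep_default_na=False)
    df["partners"] = [
        tuple(t for t in cell.split(",") if t) for cell in df["novel_partners"]
    ]
    df["n_listed"] = [len(p) for p in df["partners"]]
    return df


def novel_edge_records(unique: bool = False) -> list[EdgeRecord]:
    """The predicted novel PPIs as edge records.

    By default one record per (seed, listed partner) row listing — the
    per-gene accounting view, in which the one seed–seed pair listed under
    both endpoints appears twice (417 records).  With ``unique=True``
    canonical duplicates are collapsed (416 edges).
    """
    table = load_novel_ppi_table()
    records = [
        EdgeRecord.make(row.gene, partner, provenance="novel", source_tag="predicted")
        for row in table.itertuples(index=False)
        for partner in row.partners
    ]
    if unique:
        records = list({r.pair: r for r in records}.values())
    return records


def published_degree_table() -> pd.DataFrame:
    """Published per-seed degree accounting, ascending by known-PPI count.

    Columns: gene, K (known PPIs), N (novel PPIs), indexed as printed.
    """
    df = load_novel_ppi_table()[["gene", "n_known", "n_novel"]]
    df = df.rename(columns={"n_known": "K", "n_novel": "N"})
    return df.sort_values(["K", "gene"], kind="stable").reset_index(drop=True)
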