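"""Readers and writers for the tabular formats the pipeline consumes.

All tables are tab-separated UTF-8 text; lines starting with ``#`` are
treated as comments.  Gene identity throughout the package is the
uppercased, whitespace-stripped symbol — :func:`normalize_symbol` is the
single place that rule lives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeRecord",
    "GeneSetCollection",
    "normalize_symbol",
    "read_seed_genes",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_matrix",
]


class ValidationError(ValueError):
    """Raised when an input file or argument violates a documented contract."""


def normalize_symbol(token: str) -> str:
    """Canonical gene symbol: stripped and uppercased.

    Raises :class:`ValidationError` on empty tokens or internal whitespace.
    """
    sym = str(token).strip().upper()
    if not sym:
        raise ValidationError("empty gene symbol")
    if any(c.isspace() for c in sym):
        raise ValidationError(f"gene symbol contains whitespace: {token!r}")
    return sym


@dataclass(frozen=True)
class EdgeRecord:
    """An undirected, provenance-labelled protein–protein interaction.

    The canonical form has ``gene_a < gene_b`` lexicographically; use
    :meth:`make` to construct records in canonical form.
    """

    gene_a: str
    gene_b: str
    provenance: str = "known"  # {"known", "novel"}
    source_tag: str = ""
    score: float | None = None

    @classmethod
    def make(
        cls,
        gene_a: str,
        gene_b: str,
        provenance: str = "known",
        source_tag: str = "",
        score: float | None = None,
    ) -> "EdgeRecord":
        a, b = normalize_symbol(gene_a), normalize_symbol(gene_b)
        if a == b:
            raise ValidationError(f"self-interaction {a!r} is not a valid edge")
        if provenance not in ("known", "novel"):
            raise ValidationError(f"provenance must be 'known' or 'novel', got {provenance!r}")
        if score is not None and not (0.0 <= score <= 1.0):
            raise ValidationError(f"edge score must be in [0, 1], got {score}")
        if a > b:
            a, b = b, a
        return cls(a, b, provenance, source_tag, score)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class GeneSetCollection:
    """A named collection of gene sets with an optional background universe."""

    name: str
    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for label, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {label!r} is empty")
            if self.universe is not None and not members <= self.universe:
                raise ValidationError(
                    f"gene set {label!r} has members outside the declared universe"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


def read_seed_genes(path: str | Path, column: str = "gene") -> list[str]:
    """Read a seed-gene column from a TSV, returning a deduplicated,
    order-preserving list of canonical symbols."""
    df = _read_table(path)
    if column not in df.columns:
        raise ValidationError(f"column {column!r} not found in {path} (has {list(df.columns)})")
    seen: dict[str, None] = {}
    for token in df[column].dropna():
        seen.setdefault(normalize_symbol(token), None)
    if not seen:
        raise ValidationError(f"seed-gene column {column!r} in {path} is empty")
    return list(seen)


def read_edge_list(
    path: str | Path,
    dialect: str = "simple2col",
    provenance: str = "known",
    source_tag: str | None = None,
    strict: bool = False,
    columns: tuple[str, str] | None = None,
) -> list[EdgeRecord]:
    """Read an undirected edge list, canonicalize, and deduplicate.

    ``simple2col`` expects the first two columns to hold gene symbols (a
    header is permitted but not required); ``biogrid_tab`` expects named
    official-symbol columns for interactors A and B (BioGRID TAB dialect),
    overridable via ``columns``.  Self-pairs are dropped with a logged
    count; duplicated canonical pairs keep the first record's source tag.
    """
    path = Path(path)
    tag = source_tag if source_tag is not None else path.name
    if dialect == "simple2col":
        df = _read_table(path, header=None)
        if df.shape[1] < 2:
            raise ValidationError(f"{path}: need at least two columns, found {df.shape[1]}")
        # tolerate a header row of non-symbol labels
        pairs = df.iloc[:, :2]
        if pairs.iloc[0, 0].lower() in ("gene_a", "gene1", "source", "protein_a"):
            pairs = pairs.iloc[1:]
    elif dialect == "biogrid_tab":
        df = _read_table(path)
        col_a, col_b = columns or ("Official Symbol Interactor A", "Official Symbol Interactor B")
        missing = [c for c in (col_a, col_b) if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing BioGRID columns {missing}")
        pairs = df[[col_a, col_b]]
    else:
        raise ValidationError(f"unknown edge-list dialect {dialect!r}")

    edges: dict[tuple[str, str], EdgeRecord] = {}
    n_self = n_bad = 0
    for row in pairs.itertuples(index=False):
        a, b = row[0], row[1]
        try:
            if pd.isna(a) or pd.isna(b):
                raise ValidationError("missing symbol")
            rec = EdgeRecord.make(a, b, provenance=provenance, source_tag=tag)
        except ValidationError as exc:
            if "self-interaction" in str(exc):
                n_self += 1
                continue
            if strict:
                raise ValidationError(f"{path}: unparseable row {a!r}/{b!r}: {exc}") from exc
            n_bad += 1
            logger.warning("%s: skipping unparseable row %r/%r", path, a, b)
            continue
        edges.setdefault(rec.pair, rec)
    if n_self:
        logger.info("%s: dropped %d self-pairs", path, n_self)
    return list(edges.values())


def write_edge_list(path: str | Path, edges: Iterable[EdgeRecord]) -> None:
    """Write canonical edges as TSV, sorted for diff-stable output."""
    rows = sorted(
        {e.pair: e for e in edges}.values(), key=lambda e: (e.gene_a, e.gene_b)
    )
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tprovenance\tsource_tag\tscore\n")
        for e in rows:
            score = "" if e.score is None else f"{e.score:g}"
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.provenance}\t{e.source_tag}\t{score}\n")


def read_edge_list_tsv(path: str | Path) -> list[EdgeRecord]:
    """Read back the full-record TSV written by :func:`write_edge_list`."""
    df = _read_table(path)
    out = []
    for row in df.itertuples(index=False):
        score = float(row.score) if isinstance(row.score, str) and row.score else None
        out.append(
            EdgeRecord.make(
                row.gene_a,
                row.gene_b,
                provenance=row.provenance,
                source_tag="" if pd.isna(row.source_tag) else row.source_tag,
                score=score,
            )
        )
    return out


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (set name, description, members...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT rows need >=3 tab-separated fields"
                )
            label = fields[0]
            members = frozenset(normalize_symbol(t) for t in fields[2:] if t.strip())
            if not members:
                raise ValidationError(f"{path}: line {lineno}: gene set {label!r} is empty")
            sets[label] = members
    return GeneSetCollection(name=name or path.stem, sets=sets)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for label in sorted(collection.sets):
            members = sorted(collection.sets[label])
            fh.write("\t".join([label, collection.name] + members) + "\n")


def read_matrix(path: str | Path, orientation: str = "genes_by_rows") -> pd.DataFrame:
    """Read a gene-by-column numeric matrix; missing cells become NaN.

    ``genes_by_columns_samples`` transposes so genes always index rows.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if orientation == "genes_by_columns_samples":
        df = df.T
    elif orientation != "genes_by_rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    df.index = [normalize_symbol(g) for g in df.index]
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene rows: {sorted(set(dup))}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric cell: {exc}") from exc
    return df
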