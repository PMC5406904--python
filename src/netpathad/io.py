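"""Readers and writers for the plain-text formats the pipeline touches.

Formats: one-symbol-per-line gene lists, GMT gene-set databases, two-column
TSV / SIF edge lists, and the packaged fixtures (the transcribed pathway
table and the synthetic 430-gene disease seed list).
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable

from .datatypes import (
    GeneSet,
    Interactome,
    PathwayRecord,
    EnrichedPathwayTable,
    EnrichedPathwayRecord,
)

__all__ = [
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "load_enrichment_table",
    "load_disease_gene_fixture",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _data_text(filename: str) -> str:
    return (resources.files("netpathad") / "data" / filename).read_text(
        encoding="utf-8"
    )


def read_gene_list(path: str | Path, name: str | None = None,
                   skip_header: bool = False) -> GeneSet:
    """Read a one-symbol-per-line gene list.

    Lines beginning with ``#`` and blank lines are skipped.  ``skip_header``
    drops the first non-comment line (explicit flag; no autodetection).
    """
    path = Path(path)
    symbols: list[str] = []
    first = True
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if first and skip_header:
            first = False
            continue
        first = False
        if "\t" in line or " " in line:
            raise ParseError(
                f"{path}:{lineno}: expected a single gene symbol, got {line!r}"
            )
        symbols.append(line)
    if not symbols:
        raise ParseError(f"{path}: empty gene list")
    return GeneSet(name or path.stem, symbols)


def write_gene_list(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gs.genes)) + "\n", encoding="utf-8")


def _parse_gmt_text(text: str, origin: str, source: str) -> list[PathwayRecord]:
    records: list[PathwayRecord] = []
    seen: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{origin}:{lineno}: GMT line needs name, description and "
                f"at least one gene ({len(fields)} fields found)"
            )
        name = fields[0].strip()
        if name in seen:
            raise ParseError(
                f"{origin}:{lineno}: duplicate pathway name {name!r} "
                f"(first seen on line {seen[name]})"
            )
        seen[name] = lineno
        members = [g for g in fields[2:] if g.strip()]
        records.append(
            PathwayRecord(
                pathway_id=name,
                display_name=name,
                members=GeneSet(name, members),
                source=source,
            )
        )
    return records


def read_gmt(path: str | Path, source: str = "") -> list[PathwayRecord]:
    """Read a GMT gene-set database (name TAB description TAB gene ...)."""
    path = Path(path)
    return _parse_gmt_text(
        path.read_text(encoding="utf-8"), str(path), source or path.stem
    )


def write_gmt(records: Iterable[PathwayRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                "\t".join([r.pathway_id, r.display_name or "-"]
                          + sorted(r.members.genes)) + "\n"
            )


def read_edge_list(path: str | Path, dialect: str = "tsv2col") -> Interactome:
    """Read an undirected edge list.

    ``tsv2col``: two whitespace/tab-separated symbol columns per line.
    ``sif``: node, relation, node (the relation column is ignored; lines with
    only a node declare an isolated node).
    Comment lines (``#``) and blank lines are skipped.  Self-loops are
    dropped and reversed duplicates collapsed.
    """
    if dialect not in ("tsv2col", "sif"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")
    path = Path(path)
    net = Interactome()
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if dialect == "tsv2col":
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            net.add_edge(fields[0], fields[1])
        else:  # sif
            if len(fields) == 1:
                net = Interactome(edges=net.edges,
                                  nodes=set(net.nodes) | {fields[0]})
            elif len(fields) == 3:
                net.add_edge(fields[0], fields[2])
            else:
                raise ParseError(
                    f"{path}:{lineno}: SIF line must have 1 or 3 fields, "
                    f"got {len(fields)}"
                )
    return net


def write_edge_list(net: Interactome, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def load_enrichment_table() -> EnrichedPathwayTable:
    """Load the packaged table of enriched pathways.

    The fixture transcribes the published enrichment table for the
    Alzheimer's disease gene set: 68 pathways, each with its disease-set
    member genes, the raw Fisher exact-test p value, and the
    Benjamini-Hochberg adjusted value.
    """
    text = _data_text("enriched_pathways.tsv")
    records: list[EnrichedPathwayRecord] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 4:
            raise ParseError(
                f"enriched_pathways.tsv:{lineno}: expected 4 columns, "
                f"got {len(fields)}"
            )
        name, p_raw, p_bh, genes = fields
        records.append(
            EnrichedPathwayRecord(
                pathway_name=name.strip(),
                candidates=GeneSet(name.strip(), genes.split(",")),
                p_raw=float(p_raw),
                p_bh=float(p_bh),
            )
        )
    if not records:
        raise ParseError("enriched_pathways.tsv: fixture is empty")
    return EnrichedPathwayTable(records=tuple(records))


def load_disease_gene_fixture() -> GeneSet:
    """Load the packaged 430-symbol disease seed list.

    This fixture is a SYNTHETIC stand-in for the published supplementary
    gene list: it contains every disease-set symbol printed in the source
    publication's main text and pathway table, padded with clearly marked
    synthetic placeholder symbols (``SYNAD``-prefixed) to the published
    size of 430 genes.
    """
    text = _data_text("alzgset430_synthetic.txt")
    symbols = [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if len(symbols) == 0:
        raise ParseError("alzgset430_synthetic.txt: fixture is empty")
    return GeneSet("alzgset", symbols)


def write_tsv(rows: Iterable[dict], path: str | Path,
              columns: list[str]) -> None:
    """Small helper for the pipeline's tabular stage outputs."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
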