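"""Render a FinalList as an aligned identifier table and export it.

Conversion preserves the order/length guarantee: one output cell per input
term, with "-" standing in for anything unresolved (no match, a suggestion
still pending, a duplicate) or for a gene that simply lacks the requested
identifier. Namespaces are "symbol", "entrez", and any dbXrefs prefix
present in the index (e.g. HGNC, MIM, Ensembl).
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass
from typing import Sequence

from .errors import UnknownColumnError, UnknownNamespaceError
from .gene_db import GeneIndex
from .matcher import FinalList, MatchResult, RESOLVED_TYPES

MISSING = "-"

#: Column specifiers always available, beyond xref prefixes.
CORE_COLUMNS = ("searched_term", "match_type", "symbol", "entrez", "description")


@dataclass(frozen=True)
class FinalTable:
    columns: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValueError(
                    f"row of width {len(row)} in a {len(self.columns)}-column table"
                )


def available_namespaces(index: GeneIndex) -> set[str]:
    out = {"symbol", "entrez"}
    for rec in index.by_gene_id.values():
        out.update(rec.dbxrefs)
    return out


def _identifier(result: MatchResult, index: GeneIndex, namespace: str) -> str:
    if result.match_type not in RESOLVED_TYPES or result.gene_id is None:
        return MISSING
    rec = index.by_gene_id[result.gene_id]
    if namespace == "symbol":
        return rec.symbol
    if namespace == "entrez":
        return str(rec.gene_id)
    values = rec.dbxrefs.get(namespace)
    return values[0] if values else MISSING


def convert(fl: FinalList, index: GeneIndex, namespace: str) -> list[str]:
    """One identifier string per input term, in input order."""
    if namespace not in available_namespaces(index):
        raise UnknownNamespaceError(namespace, available_namespaces(index))
    return [_identifier(r, index, namespace) for r in fl.results]


def _cell(result: MatchResult, index: GeneIndex, column: str) -> str:
    if column == "searched_term":
        return result.term
    if column == "match_type":
        return result.match_type.label
    if column == "description":
        if result.match_type in RESOLVED_TYPES and result.gene_id is not None:
            return index.by_gene_id[result.gene_id].description or MISSING
        return MISSING
    return _identifier(result, index, column)


def to_table(
    fl: FinalList, index: GeneIndex, columns: Sequence[str]
) -> FinalTable:
    """Assemble the Final Table, one row per input term in input order."""
    valid = set(CORE_COLUMNS) | available_namespaces(index)
    for col in columns:
        if col not in valid:
            raise UnknownColumnError(
                f"unknown column {col!r}; available: {', '.join(sorted(valid))}"
            )
    rows = tuple(
        tuple(_cell(r, index, col) for col in columns) for r in fl.results
    )
    return FinalTable(columns=tuple(columns), rows=rows)


def write_csv(table: FinalTable, sink) -> None:
    """Write *table* as RFC 4180 CSV (UTF-8, header row first).

    *sink* is a path or a text stream. Entrez IDs are written as plain
    integers, never with thousands separators.
    """
    if isinstance(sink, (str, bytes, os.PathLike)):
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            _write_csv_stream(table, fh)
    else:
        _write_csv_stream(table, sink)


def _write_csv_stream(table: FinalTable, stream: io.TextIOBase) -> None:
    writer = csv.writer(stream)
    writer.writerow(table.columns)
    writer.writerows(table.rows)


def write_id_list(ids: Sequence[str], sink) -> None:
    """Write identifiers one per line (the plain-text export)."""
    text = "".join(f"{i}\n" for i in ids)
    if isinstance(sink, (str, bytes, os.PathLike)):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        sink.write(text)
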