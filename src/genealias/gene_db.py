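"""NCBI gene_info parsing and the per-taxon lookup index.

The gene_info dialect is tab-separated with the NCBI column order
(tax_id, GeneID, Symbol, LocusTag, Synonyms, dbXrefs, chromosome,
map_location, description, type_of_gene, ...); columns beyond the tenth vary
by release and are ignored. "-" marks an absent field, Synonyms is
pipe-separated, and dbXrefs is pipe-separated prefix:value pairs. Files may
be gzip-compressed (detected by magic bytes, not filename).

One matching session works against a single taxon, so :func:`build_index`
requires all records to share a tax_id and official symbols to be unique
within it.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from .errors import GeneInfoParseError, IndexBuildError
from .normalizer import canonical_key

logger = logging.getLogger(__name__)

GENE_INFO_COLUMNS = (
    "tax_id", "GeneID", "Symbol", "LocusTag", "Synonyms", "dbXrefs",
    "chromosome", "map_location", "description", "type_of_gene",
)

#: NCBI bookkeeping placeholder rows, not genes.
_PLACEHOLDER_SYMBOL = "NEWENTRY"


@dataclass(frozen=True)
class GeneRecord:
    """One gene as parsed from a gene_info row."""

    tax_id: int
    gene_id: int
    symbol: str
    synonyms: tuple[str, ...] = ()
    dbxrefs: dict[str, tuple[str, ...]] = field(default_factory=dict)
    description: str = ""
    type_of_gene: str = ""

    def __post_init__(self):
        if self.gene_id <= 0:
            raise ValueError(f"gene_id must be positive, got {self.gene_id}")
        if not self.symbol:
            raise ValueError("symbol must be non-empty")
        if any(not s for s in self.synonyms):
            raise ValueError(f"gene {self.gene_id}: empty synonym")
        if self.symbol in self.synonyms:
            raise ValueError(
                f"gene {self.gene_id}: symbol {self.symbol!r} repeated in synonyms"
            )
        for prefix, values in self.dbxrefs.items():
            if any(not v for v in values):
                raise ValueError(
                    f"gene {self.gene_id}: empty dbxref value under {prefix!r}"
                )


class SynonymEntry(NamedTuple):
    """One scan target for the substring-suggestion tier."""

    target: str
    is_official: bool
    gene_id: int


@dataclass(frozen=True)
class GeneIndex:
    """Per-taxon lookup structures over a set of :class:`GeneRecord`.

    ``by_symbol_key`` maps a canonical symbol key to the tuple of gene_ids
    whose official symbols share it (almost always one; the auto-accept tier
    must see collisions, hence a tuple).
    """

    tax_id: int
    by_symbol_key: dict[str, tuple[int, ...]]
    by_exact_symbol: dict[str, int]
    by_xref: dict[str, int]
    synonym_entries: tuple[SynonymEntry, ...]
    by_gene_id: dict[int, GeneRecord]

    def __len__(self) -> int:
        return len(self.by_gene_id)


def parse_dbxrefs(fieldtext: str) -> dict[str, tuple[str, ...]]:
    """Parse a dbXrefs field into {prefix: (values...)}.

    Items split on the FIRST colon only, so nested HGNC identifiers keep
    their prefix in the value: "HGNC:HGNC:11766" -> {"HGNC": ("HGNC:11766",)}.
    Unknown prefixes are retained verbatim. "-" yields an empty map. An item
    with no colon is recorded under the empty prefix with a warning.
    """
    if fieldtext in ("", "-"):
        return {}
    out: dict[str, list[str]] = {}
    for item in fieldtext.split("|"):
        if not item:
            continue
        prefix, sep, value = item.partition(":")
        if not sep:
            logger.warning("dbXref item %r has no colon; recording under empty prefix", item)
            prefix, value = "", item
        if not value:
            logger.warning("dbXref item %r has an empty value; skipped", item)
            continue
        out.setdefault(prefix, []).append(value)
    return {k: tuple(v) for k, v in out.items()}


def _open_source(source) -> tuple[Iterable[str], bool]:
    """Return (line iterable, we_opened_it). Paths may be gzip-compressed."""
    if isinstance(source, (str, bytes, os.PathLike)):
        with open(source, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(source, "rt", encoding="utf-8"), True
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _parse_int(text: str, line_no: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise GeneInfoParseError(line_no, f"non-integer {what}: {text!r}") from None


def parse_gene_info(source, taxon_filter: int | None = None) -> list[GeneRecord]:
    """Parse a gene_info-dialect source into gene records.

    *source* is a path (plain or gzip) or an iterable of text lines. Header
    lines starting with "#" and blank lines are skipped, as are NCBI
    "NEWENTRY" placeholder rows and, when *taxon_filter* is given, rows of
    other taxa. Raises :class:`GeneInfoParseError` (naming the line number)
    on rows with fewer than 10 columns or non-integer tax_id/GeneID.
    """
    lines, opened = _open_source(source)
    records: list[GeneRecord] = []
    try:
        for line_no, raw in enumerate(lines, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise GeneInfoParseError(
                    line_no,
                    f"expected at least 10 tab-separated columns, found {len(cols)}",
                )
            tax_id = _parse_int(cols[0], line_no, "tax_id")
            if taxon_filter is not None and tax_id != taxon_filter:
                continue
            gene_id = _parse_int(cols[1], line_no, "GeneID")
            symbol = cols[2]
            if symbol == _PLACEHOLDER_SYMBOL:
                continue
            if not symbol or symbol == "-":
                raise GeneInfoParseError(line_no, "missing Symbol")
            syn_field = cols[4]
            synonyms = tuple(
                s for s in (syn_field.split("|") if syn_field not in ("", "-") else ())
                if s and s != symbol
            )
            records.append(
                GeneRecord(
                    tax_id=tax_id,
                    gene_id=gene_id,
                    symbol=symbol,
                    synonyms=synonyms,
                    dbxrefs=parse_dbxrefs(cols[5]),
                    description="" if cols[8] == "-" else cols[8],
                    type_of_gene="" if cols[9] == "-" else cols[9],
                )
            )
    finally:
        if opened:
            lines.close()
    return records


def build_index(records: Iterable[GeneRecord]) -> GeneIndex:
    """Build the per-taxon :class:`GeneIndex`.

    by_xref maps, per gene: the Entrez ID as a string, every dbxref value
    verbatim, and for nested values like "HGNC:11766" also the tail after the
    last colon ("11766"), so bare HGNC numbers resolve too. When two genes
    claim the same xref string the first (in record order) wins and a warning
    is logged. Duplicate official symbols raise :class:`IndexBuildError`.
    """
    records = list(records)
    if not records:
        return GeneIndex(0, {}, {}, {}, (), {})

    taxa = {r.tax_id for r in records}
    if len(taxa) > 1:
        raise IndexBuildError(f"records span multiple taxa: {sorted(taxa)}")
    (tax_id,) = taxa

    by_exact_symbol: dict[str, int] = {}
    for r in records:
        if r.symbol in by_exact_symbol:
            raise IndexBuildError(
                f"duplicate official symbol {r.symbol!r} "
                f"(gene_ids {by_exact_symbol[r.symbol]} and {r.gene_id})"
            )
        by_exact_symbol[r.symbol] = r.gene_id

    by_symbol_key: dict[str, list[int]] = {}
    by_xref: dict[str, int] = {}
    entries: list[SynonymEntry] = []
    by_gene_id: dict[int, GeneRecord] = {}

    def add_xref(key: str, gene_id: int) -> None:
        prior = by_xref.setdefault(key, gene_id)
        if prior != gene_id:
            logger.warning(
                "xref %r claimed by gene %d and gene %d; keeping the first",
                key, prior, gene_id,
            )

    for r in records:
        by_gene_id[r.gene_id] = r
        by_symbol_key.setdefault(canonical_key(r.symbol), []).append(r.gene_id)
        add_xref(str(r.gene_id), r.gene_id)
        for values in r.dbxrefs.values():
            for value in values:
                add_xref(value, r.gene_id)
                if ":" in value:
                    add_xref(value.rsplit(":", 1)[1], r.gene_id)
        entries.append(SynonymEntry(r.symbol, True, r.gene_id))
        entries.extend(SynonymEntry(s, False, r.gene_id) for s in r.synonyms)

    return GeneIndex(
        tax_id=tax_id,
        by_symbol_key={k: tuple(v) for k, v in by_symbol_key.items()},
        by_exact_symbol=by_exact_symbol,
        by_xref=by_xref,
        synonym_entries=tuple(entries),
        by_gene_id=by_gene_id,
    )
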