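"""Deterministic generation of gene_info-dialect files.

Every other module is testable offline through this one: it writes the
dialect that :func:`genealias.gene_db.parse_gene_info` reads, provides a
frozen 12-gene human reference set (inflammation-related genes whose obsolete
aliases are classic disambiguation cases, plus decoy paralogues and a
pseudogene that make those aliases genuinely ambiguous), and builds seeded
random databases for property testing. Synonym and cross-reference content
of the frozen set mirrors an NCBI gene_info snapshot; nothing is fetched at
run time.
"""

from __future__ import annotations

import os
import random
import string
from dataclasses import dataclass, field

from .gene_db import GeneRecord

GENE_INFO_HEADER = (
    "#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs\t"
    "chromosome\tmap_location\tdescription\ttype_of_gene"
)

HUMAN_TAX_ID = 9606


@dataclass(frozen=True)
class FixtureGene:
    gene_id: int
    symbol: str
    synonyms: tuple[str, ...] = ()
    dbxrefs: dict[str, tuple[str, ...]] = field(default_factory=dict)
    description: str = ""
    type_of_gene: str = "protein-coding"


@dataclass(frozen=True)
class FixtureSpec:
    """An ordered gene set for one taxon, writable as gene_info."""

    tax_id: int
    genes: tuple[FixtureGene, ...]

    def __post_init__(self):
        symbols = [g.symbol for g in self.genes]
        ids = [g.gene_id for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("fixture symbols must be unique")
        if len(set(ids)) != len(ids):
            raise ValueError("fixture gene_ids must be unique")

    def to_records(self) -> list[GeneRecord]:
        return [
            GeneRecord(
                tax_id=self.tax_id,
                gene_id=g.gene_id,
                symbol=g.symbol,
                synonyms=g.synonyms,
                dbxrefs=dict(g.dbxrefs),
                description=g.description,
                type_of_gene=g.type_of_gene,
            )
            for g in self.genes
        ]


def _xrefs(mim: int | None = None, hgnc: int | None = None,
           ensembl: str | None = None) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    if mim is not None:
        out["MIM"] = (str(mim),)
    if hgnc is not None:
        out["HGNC"] = (f"HGNC:{hgnc}",)
    if ensembl is not None:
        out["Ensembl"] = (ensembl,)
    return out


def canonical_human_fixture() -> FixtureSpec:
    """The frozen human reference set.

    Nine inflammation-related genes commonly cited by obsolete aliases
    (IL8, MCP1, TNFA, TGFB, MYPT1 ...) plus three decoys — the CXCR2P1
    pseudogene and the TGFB2/TGFB3 paralogues — whose symbols and synonyms
    overlap the aliases, so that suggestion ranking has real ambiguity to
    resolve.
    """
    genes = (
        FixtureGene(7040, "TGFB1", ("TGFB", "TGFBETA", "DPD1", "LAP"),
                    _xrefs(190180, 11766, "ENSG00000105329"),
                    "transforming growth factor beta 1"),
        FixtureGene(3576, "CXCL8", ("IL8", "GCP-1", "LUCT", "MDNCF"),
                    _xrefs(146930, 6025, "ENSG00000169429"),
                    "C-X-C motif chemokine ligand 8"),
        FixtureGene(6347, "CCL2", ("MCP1", "MCAF", "SCYA2"),
                    _xrefs(158105, 10618, "ENSG00000108691"),
                    "C-C motif chemokine ligand 2"),
        FixtureGene(1401, "CRP", ("PTX1",),
                    _xrefs(123260, 2367, "ENSG00000132693"),
                    "C-reactive protein"),
        FixtureGene(7124, "TNF", ("TNFA", "DIF", "TNFSF2"),
                    _xrefs(191160, 11892, "ENSG00000232810"),
                    "tumor necrosis factor"),
        FixtureGene(3577, "CXCR1", ("IL8RA", "CD181", "CKR-1"),
                    _xrefs(146929, 6026, "ENSG00000163464"),
                    "C-X-C motif chemokine receptor 1"),
        FixtureGene(3579, "CXCR2", ("IL8RB", "CD182"),
                    _xrefs(146928, 6027, "ENSG00000180871"),
                    "C-X-C motif chemokine receptor 2"),
        FixtureGene(729230, "CCR2", ("MCP1R", "CD192", "CKR2", "CMKBR2"),
                    _xrefs(601267, 1603, "ENSG00000121807"),
                    "C-C motif chemokine receptor 2"),
        FixtureGene(4659, "PPP1R12A", ("MYPT1", "M130", "MBS"),
                    _xrefs(602021, 7618, "ENSG00000058272"),
                    "protein phosphatase 1 regulatory subunit 12A"),
        # Decoys: overlap the aliases above without being the intended hit.
        FixtureGene(3580, "CXCR2P1", ("IL8RBP",),
                    _xrefs(hgnc=6028),
                    "C-X-C motif chemokine receptor 2 pseudogene 1",
                    type_of_gene="pseudo"),
        FixtureGene(7042, "TGFB2", ("LDS4", "G-TSF"),
                    _xrefs(190220, 11768, "ENSG00000092969"),
                    "transforming growth factor beta 2"),
        FixtureGene(7043, "TGFB3", ("ARVD1", "LDS5"),
                    _xrefs(190230, 11769, "ENSG00000119699"),
                    "transforming growth factor beta 3"),
    )
    return FixtureSpec(tax_id=HUMAN_TAX_ID, genes=genes)


def _row(tax_id: int, g: FixtureGene) -> str:
    xrefs = "|".join(
        f"{prefix}:{value}"
        for prefix, values in g.dbxrefs.items()
        for value in values
    )
    fields = (
        str(tax_id),
        str(g.gene_id),
        g.symbol,
        "-",
        "|".join(g.synonyms) or "-",
        xrefs or "-",
        "-",
        "-",
        g.description or "-",
        g.type_of_gene or "-",
    )
    return "\t".join(fields)


def write_gene_info(spec: FixtureSpec, sink) -> None:
    """Emit *spec* in the gene_info dialect (header plus one row per gene).

    Round-trips: parsing the output reproduces ``spec.to_records()``.
    *sink* is a path or a text stream.
    """
    text = "".join(
        [GENE_INFO_HEADER + "\n"] + [_row(spec.tax_id, g) + "\n" for g in spec.genes]
    )
    if isinstance(sink, (str, bytes, os.PathLike)):
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        sink.write(text)


def random_fixture(
    seed: int,
    n_genes: int,
    max_synonyms: int = 3,
    tax_id: int = HUMAN_TAX_ID,
) -> FixtureSpec:
    """Seeded random gene set for property tests.

    Symbols are unique random letter strings (optionally digit-suffixed);
    about half of all synonyms are another gene's symbol plus a random
    suffix, so substring-suggestion paths are exercised; some genes carry
    HGNC/MIM-style cross-references.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = random.Random(seed)
    letters = string.ascii_uppercase

    symbols: list[str] = []
    seen: set[str] = set()
    while len(symbols) < n_genes:
        sym = "".join(rng.choices(letters, k=rng.randint(3, 6)))
        if rng.random() < 0.5:
            sym += str(rng.randint(1, 9))
        if sym not in seen:
            seen.add(sym)
            symbols.append(sym)

    gene_ids = rng.sample(range(1000, 1_000_000), n_genes)

    genes: list[FixtureGene] = []
    for i, (gid, sym) in enumerate(zip(gene_ids, symbols)):
        synonyms: list[str] = []
        for _ in range(rng.randint(0, max_synonyms)):
            if n_genes > 1 and rng.random() < 0.5:
                base = symbols[rng.randrange(n_genes)]
                syn = base + "".join(rng.choices(letters, k=2))
            else:
                syn = "".join(rng.choices(letters, k=rng.randint(2, 7)))
            if syn != sym and syn not in synonyms:
                synonyms.append(syn)
        dbxrefs: dict[str, tuple[str, ...]] = {}
        if rng.random() < 0.4:
            dbxrefs["HGNC"] = (f"HGNC:{rng.randint(1, 99999)}",)
        if rng.random() < 0.4:
            dbxrefs["MIM"] = (str(rng.randint(100000, 699999)),)
        genes.append(
            FixtureGene(
                gene_id=gid,
                symbol=sym,
                synonyms=tuple(synonyms),
                dbxrefs=dbxrefs,
                description=f"random gene {i}",
            )
        )
    return FixtureSpec(tax_id=tax_id, genes=tuple(genes))
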