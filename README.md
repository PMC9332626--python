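# genealias

Gene alias disambiguation and identifier conversion for anyone who has ever
been handed a gene list full of names like *IL-8*, *MCP-1* or *TGF-β* and
needed official symbols or Entrez IDs out the other end.

Gene nomenclature is not uniform across databases, analysis tools, or the
literature: obsolete aliases (IL8 for CXCL8, MCP1 for CCL2) and colloquial
spellings with Greek characters (TNF-α) persist in publications and
supplementary tables, and most ID-conversion tools simply fail on them.
`genealias` resolves free-form gene terms — official symbols, old aliases,
or database identifiers (Entrez, HGNC, OMIM, Ensembl, ...) — against an
NCBI `gene_info` annotation file, and converts between identifier
namespaces, without asking you to declare what kind of identifier you are
holding. The output list always has the same order and length as the input,
so row *i* out is row *i* in.

## The matching algorithm

Each searched term passes through tiers, stopping at the first hit:

1. **Exact match** — the term, verbatim, equals an official NCBI symbol or
   an indexed cross-reference string (a numeric Entrez ID, `HGNC:11766`, a
   bare HGNC/OMIM number, an `ENSG…` accession). This is how identifier
   conversion works with no input-type selector.
2. **Auto-accepted suggestion** — a normalized variant of the term (case
   folded; hyphens/underscores/whitespace stripped; Greek letters replaced
   by their Latin initial, β→B, or spelled name, β→BETA) keys to exactly
   one official symbol. `TGF-β1 → TGFB1`. If variants hit two or more
   symbols the term is ambiguous and falls through.
3. **Suggestions** — a variant is a substring of a gene synonym or symbol
   (case-insensitive). Candidates are ranked: exact synonym hits first
   (`IL8` is *the* synonym of CXCL8), then shorter matched targets, then
   ascending Entrez ID. The user picks one, or `--auto-top` takes rank 1.
4. Otherwise **No Match**; repeated raw terms are flagged **Duplicate
   Term**. Both keep their row in the output.

Duplicate detection compares raw terms, so `IL-8` and `IL8` are distinct
searches.

## Worked example

A bundled, frozen 12-gene human reference set (nine inflammation-related
genes plus decoy paralogues and a pseudogene) makes everything runnable
offline:

```sh
genealias fixture --canonical -o human.tsv
genealias match --db human.tsv --auto-top \
    "TGF-β" "IL-8" "MCP-1" CRP "TNF-α" CXCR1 CXCR2 CCR2 MYPT1 "TGF-β1"
```

prints the Final Table as CSV:

```
searched_term,match_type,symbol
TGF-β,Suggestion Accepted,TGFB1
IL-8,Suggestion Accepted,CXCL8
MCP-1,Suggestion Accepted,CCL2
CRP,Exact Match,CRP
TNF-α,Suggestion Accepted,TNF
CXCR1,Exact Match,CXCR1
CXCR2,Exact Match,CXCR2
CCR2,Exact Match,CCR2
MYPT1,Suggestion Accepted,PPP1R12A
TGF-β1,Auto-accepted Suggestion,TGFB1
```

with a summary on stderr: `exact=4 auto-accepted=1 accepted=5 pending=0
no-match=0 duplicate=0`. Four terms were already official symbols; TGF-β1
normalized uniquely to TGFB1; the other five were ambiguous aliases whose
top-ranked suggestion was accepted (`IL-8`, for instance, suggests CXCL8,
CXCR1, CXCR2 and CXCR2P1, with CXCL8 first because `IL8` matches its
synonym exactly). Conversion works the same way:

```sh
$ genealias convert --db human.tsv --to entrez --auto-top "TGF-β" "IL-8" CRP
7040
3576
1401
```

Every term, alias or not, comes back with an Entrez ID — the point of
disambiguating before converting. For real work, download a full per-taxon
annotation (`genealias fetch -o Homo_sapiens.gene_info.gz`, or any NCBI
`gene_info` dump; gzip is detected automatically) and pass it as `--db`.

The same functionality is available as a library:

```python
from genealias import (canonical_human_fixture, build_index, match_list, convert)
index = build_index(canonical_human_fixture().to_records())
fl = match_list(["IL-8", "CRP"], index, auto_top=True)
convert(fl, index, "entrez")   # ['3576', '1401']
```

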