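# Methods

## Problem and data model

The package resolves free-form gene terms against the NCBI `gene_info`
annotation dialect: one tab-separated row per gene with tax_id, GeneID
(Entrez), official Symbol, Synonyms (pipe-separated), and dbXrefs
(pipe-separated `prefix:value` cross-references such as `MIM:190180`,
`HGNC:HGNC:11766`, `Ensembl:ENSG00000105329`). Columns beyond the tenth
vary across NCBI releases and are ignored. A `dbXrefs` item is split on the
*first* colon only, so nested HGNC identifiers keep their inner prefix in
the value; unknown prefixes are retained verbatim, which is how
taxon-specific resources (FLYBASE, WormBase, ...) pass through untouched.
`NEWENTRY` rows are NCBI bookkeeping placeholders and are dropped. Gzip
input is recognised by magic bytes rather than filename, since users rename
downloads.

A matching session is scoped to one taxon (default 9606). The index built
over the records holds: a verbatim symbol map, a canonical-key symbol map,
a cross-reference map (every dbXref value verbatim, the Entrez ID as a
string, and the numeric tail of nested values so a bare `11766` resolves),
and a flat scan list of synonyms and symbols for the substring tier. When
two genes claim the same cross-reference string the first in file order
wins and a warning is logged; official-symbol duplicates within a taxon are
an error, because they break the premise of disambiguation.

## Term normalization

Obsolete aliases differ from official symbols mainly by case, separator
characters, and Greek letters. Each term generates an ordered,
de-duplicated variant list: the original; the uppercased form; the form
with `-`/`_`/whitespace removed; Greek characters replaced by Latin
initial (β→B) and, separately, by spelled name (β→BETA); and all
combinations — at most 7 variants, so pathological input cannot blow up.
Two deliberate choices:

- **Replacement, not deletion.** Deleting β from `TGF-β1` gives `TGF1`,
  which names nothing; substitution gives `TGFB1`, the official symbol.
- **Both Greek modes.** Official symbols use the initial (`TGFB1`), but
  many NCBI synonyms spell the name out (`TGFBETA`), so both are generated
  and matched.

The Greek repertoire is the set occurring in gene nomenclature (α β γ δ ε κ
λ, both cases); anything else passes through unchanged. The canonical
lookup key (uppercase, separators stripped) is shared by the index and the
matcher and is idempotent; variant generation is closed under itself — no
variant of a variant introduces a new canonical key — which the property
suite checks.

## Tier semantics and edge decisions

Tiers apply in order: duplicate, exact, auto-accept, substring suggestion,
no-match. Points where the behaviour was genuinely open, and the choices
made:

- **Exact means verbatim.** A pure case change (`crp`) is an auto-accepted
  suggestion, not an exact match: the user did not type the official
  symbol, and the distinction is worth surfacing.
- **Auto-accept requires uniqueness.** If variants of a term key to two or
  more official symbols, silently picking one would defeat the purpose of
  disambiguation; the term falls to the suggestion tier. This is why
  `TGF-β` (whose variants reach TGFB1, TGFB2 and TGFB3) is a user decision
  while `TGF-β1` is auto-accepted.
- **Substring direction is variant-in-target only** (`IL8` ⊂ `IL8RA`), over
  synonyms *and* official symbols, compared casefolded. Including symbols
  lets `TGF-β` suggest the TGFB2/TGFB3 paralogues, which a curator should
  see. Variants shorter than 2 characters are excluded from the scan —
  single letters match nearly everything.
- **Ranking**: exact synonym hits first (the strongest evidence an alias
  points at a gene), then shorter matched targets (a tighter containment),
  then ascending Entrez ID. The key is total, so suggestion order is
  deterministic and independent of candidate enumeration order; one scan
  target per gene is kept (the best-scoring one).
- **Duplicates are detected on raw terms**, casefolded, not on normalized
  variants: `IL-8` and `IL8` are different searches that happen to resolve
  alike, and flagging the second as a duplicate would hide that.

The output list always has one result per input term with positions
0..n−1; no tier can drop or reorder rows. Pending suggestions are resolved
either interactively (`accept_suggestion`, which returns a new result list
and touches nothing else) or wholesale with `auto_top`, which takes each
rank-1 suggestion — the non-interactive analogue of a user accepting every
default.

## Conversion

Conversion renders resolved rows in a target namespace: `symbol`,
`entrez`, or any dbXrefs prefix present in the database. Unresolved rows
(no match, still pending, duplicate) and genes lacking the requested
identifier render as `-`, keeping alignment. CSV export is RFC 4180,
UTF-8, header row first; Entrez IDs are written as plain integers (a
rendered `729,230` is display formatting, not data). Where a gene carries
several values under one prefix the first is used.

## Reference and synthetic databases

The frozen human reference set contains nine inflammation-related genes
that are classic alias-disambiguation cases (CRP; CXCL8/IL8; CCL2/MCP1;
TNF/TNFA; TGFB1/TGFB/TGFBETA; CXCR1/IL8RA; CXCR2/IL8RB; CCR2/MCP1R;
PPP1R12A/MYPT1) plus three decoys — the CXCR2P1 pseudogene (synonym
IL8RBP) and the TGFB2/TGFB3 paralogues — chosen so the aliases above are
*genuinely* ambiguous: IL-8 must rank CXCL8 above three receptor genes,
and TGF-β must rank TGFB1 above its paralogues. Symbols, Entrez IDs,
synonyms and HGNC/MIM/Ensembl cross-references mirror an NCBI `gene_info`
snapshot and are frozen in the source; nothing is downloaded at run or
test time.

What this set does *not* emulate: NCBI scale (tens of thousands of genes
per taxon, where the substring scan meets far more incidental hits),
synonym collisions across distant gene families, non-human taxa, and
discontinued GeneIDs (the `gene_history` file is out of scope). Passing
tests therefore demonstrate the algorithm's correctness on a database
whose ambiguity structure is realistic but small; they do not bound
suggestion-list sizes on a full annotation.

The seeded random generator (`random_fixture`) produces unique random
symbols and Entrez IDs, draws roughly half of all synonyms as another
gene's symbol plus a random suffix (so the substring tier always has work
to do), and sprinkles HGNC/MIM-style cross-references. It exists for
property testing: write→parse round-trips, order/length conservation, and
agreement of the indexed matcher with a brute-force scan that re-derives
every tier by nested loops over the raw records (50 genes, 200 queries,
fixed seeds — small enough to run in well under a second, large enough
that every tier and tie-break fires).

## Numerical / procedural choices

- All matching is string-based; there are no tolerances. Determinism is an
  explicit contract: identical inputs produce byte-identical outputs, and
  data outputs carry no timestamps.
- Tie-breaks everywhere end in ascending Entrez ID, the only stable
  arbiter available.
- Degenerate inputs: empty term lists produce empty (header-only) outputs;
  empty or whitespace-only search terms are rejected at variant
  generation; an empty record collection builds an empty index.
- `scripts/acceptance.py` runs the full pipeline (generate → write →
  parse → index → match → convert) on the ten-term panel; the pipeline has
  no stochastic step, so the `--seed` argument only feeds an auxiliary
  shuffled-input conservation check.

## Known limitations

- No fuzzy matching: misspellings beyond case/separator/Greek variation
  (e.g. transposed letters) fall to the substring tier or to No Match;
  edit-distance suggestion is deliberately out of scope.
- One taxon per session; cross-taxon search and orthology mapping are
  non-goals.
- The substring tier can over-suggest on very short aliases against a
  full-size annotation; ranking mitigates but does not eliminate this.
- Discontinued or merged GeneIDs are not tracked; the database snapshot
  provided by the operator is taken as ground truth.
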