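"""Tiered classification of searched terms and suggestion resolution.

Each input term goes through the tiers in order:

0. **Duplicate** — the raw term (casefolded) was already searched.
1. **Exact** — the term, verbatim, is an official symbol or an indexed
   cross-reference/Entrez string. Identifier inputs therefore resolve
   without the user declaring the input type.
2. **Auto-accepted** — some normalized variant (never the verbatim term)
   keys to exactly one official symbol. A pure case change lands here, not
   at tier 1. If variants hit two or more distinct official symbols the
   term is ambiguous and falls through to the suggestion tier.
3. **Suggestion** — some variant (length >= 2) is a casefold substring of a
   synonym or an official symbol. Candidates are ranked with exact synonym
   hits first, then shorter targets, then ascending Entrez ID; the user (or
   ``auto_top``) picks one.
4. **No match.**

Whatever happens, the output list has the same order and length as the
input list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
import re
from typing import Iterable, Sequence

from .errors import SuggestionStateError
from .gene_db import GeneIndex, SynonymEntry
from .normalizer import TermVariants, canonical_key, variants

_TOKEN_SPLIT = re.compile(r"[,\s]+")

#: Minimum variant length admitted to the substring tier; single characters
#: would match nearly every synonym.
MIN_SUBSTRING_LEN = 2


class MatchType(Enum):
    """Classification of one searched term; values are the display labels."""

    EXACT = "Exact Match"
    AUTO_ACCEPTED = "Auto-accepted Suggestion"
    SUGGESTION_PENDING = "Suggestion Pending"
    SUGGESTION_ACCEPTED = "Suggestion Accepted"
    NO_MATCH = "No Match"
    DUPLICATE = "Duplicate Term"

    @property
    def label(self) -> str:
        return self.value


#: Match types carrying a resolved gene.
RESOLVED_TYPES = frozenset(
    {MatchType.EXACT, MatchType.AUTO_ACCEPTED, MatchType.SUGGESTION_ACCEPTED}
)


@dataclass(frozen=True)
class Suggestion:
    gene_id: int
    matched_target: str
    exact_synonym: bool
    rank: int


@dataclass(frozen=True)
class MatchResult:
    term: str
    position: int
    match_type: MatchType
    gene_id: int | None = None
    suggestions: tuple[Suggestion, ...] = ()
    duplicate_of: int | None = None

    def __post_init__(self):
        if (self.gene_id is not None) != (self.match_type in RESOLVED_TYPES):
            raise ValueError(
                f"gene_id must be present iff resolved; got {self.match_type} "
                f"with gene_id={self.gene_id}"
            )
        if (self.duplicate_of is not None) != (self.match_type is MatchType.DUPLICATE):
            raise ValueError("duplicate_of must be present iff DUPLICATE")


@dataclass(frozen=True)
class FinalList:
    """Ordered results, one per input term, positions 0..n-1."""

    tax_id: int
    results: tuple[MatchResult, ...]

    def __post_init__(self):
        for i, r in enumerate(self.results):
            if r.position != i:
                raise ValueError(f"result at index {i} has position {r.position}")

    def __len__(self) -> int:
        return len(self.results)

    def counts(self) -> dict[MatchType, int]:
        out = {mt: 0 for mt in MatchType}
        for r in self.results:
            out[r.match_type] += 1
        return out


def tokenize_input(raw: str) -> list[str]:
    """Split free text into search terms on commas and whitespace."""
    return [t for t in _TOKEN_SPLIT.split(raw) if t]


def rank_suggestions(
    tv: TermVariants, candidates: Iterable[SynonymEntry]
) -> tuple[Suggestion, ...]:
    """Order candidates: exact synonym hits first, then shorter matched
    targets, then ascending gene_id. Candidates must already be de-duplicated
    by gene (best target per gene)."""
    variant_keys = {v.casefold() for v in tv.variants}
    scored = sorted(
        candidates,
        key=lambda c: (
            c.target.casefold() not in variant_keys,
            len(c.target),
            c.gene_id,
        ),
    )
    return tuple(
        Suggestion(
            gene_id=c.gene_id,
            matched_target=c.target,
            exact_synonym=c.target.casefold() in variant_keys,
            rank=i + 1,
        )
        for i, c in enumerate(scored)
    )


def _substring_candidates(tv: TermVariants, index: GeneIndex) -> list[SynonymEntry]:
    """Best-matching scan target per gene, for variants of length >= 2."""
    usable = [v.casefold() for v in tv.variants if len(v) >= MIN_SUBSTRING_LEN]
    best: dict[int, tuple[tuple, SynonymEntry]] = {}
    for entry in index.synonym_entries:
        tf = entry.target.casefold()
        matched = exact = False
        for v in usable:
            if v in tf:
                matched = True
                if v == tf:
                    exact = True
                    break
        if not matched:
            continue
        key = (not exact, len(entry.target), entry.target)
        prior = best.get(entry.gene_id)
        if prior is None or key < prior[0]:
            best[entry.gene_id] = (key, entry)
    return [pair[1] for pair in best.values()]


def classify_term(
    term: str,
    index: GeneIndex,
    prior_terms: Sequence[str],
    position: int | None = None,
) -> MatchResult:
    """Classify one term through the tiers; *prior_terms* are the raw terms
    already searched (for duplicate detection), and *position* defaults to
    ``len(prior_terms)``."""
    if position is None:
        position = len(prior_terms)

    folded = term.casefold()
    for i, prior in enumerate(prior_terms):
        if prior.casefold() == folded:
            return MatchResult(term, position, MatchType.DUPLICATE, duplicate_of=i)

    gene_id = index.by_exact_symbol.get(term)
    if gene_id is None:
        gene_id = index.by_xref.get(term)
    if gene_id is not None:
        return MatchResult(term, position, MatchType.EXACT, gene_id=gene_id)

    tv = variants(term)
    symbol_hits: list[int] = []
    for v in tv.variants[1:]:
        for gid in index.by_symbol_key.get(canonical_key(v), ()):
            if gid not in symbol_hits:
                symbol_hits.append(gid)
    if len(symbol_hits) == 1:
        return MatchResult(
            term, position, MatchType.AUTO_ACCEPTED, gene_id=symbol_hits[0]
        )

    candidates = _substring_candidates(tv, index)
    if candidates:
        return MatchResult(
            term,
            position,
            MatchType.SUGGESTION_PENDING,
            suggestions=rank_suggestions(tv, candidates),
        )

    return MatchResult(term, position, MatchType.NO_MATCH)


def match_list(
    terms: Sequence[str], index: GeneIndex, auto_top: bool = False
) -> FinalList:
    """Classify every term left to right into a :class:`FinalList`.

    With ``auto_top`` each pending suggestion is resolved to its rank-1
    candidate, for non-interactive pipelines.
    """
    results: list[MatchResult] = []
    prior: list[str] = []
    for i, term in enumerate(terms):
        r = classify_term(term, index, prior, position=i)
        if auto_top and r.match_type is MatchType.SUGGESTION_PENDING and r.suggestions:
            r = replace(
                r,
                match_type=MatchType.SUGGESTION_ACCEPTED,
                gene_id=r.suggestions[0].gene_id,
            )
        results.append(r)
        prior.append(term)
    return FinalList(tax_id=index.tax_id, results=tuple(results))


def accept_suggestion(fl: FinalList, position: int, gene_id: int) -> FinalList:
    """Resolve the pending suggestion at *position* to *gene_id*.

    Returns a new :class:`FinalList`; every other result is untouched.
    Raises :class:`SuggestionStateError` if the position is out of range, the
    result is not pending, or the gene was not among its suggestions.
    """
    if not 0 <= position < len(fl.results):
        raise SuggestionStateError(
            f"position {position} out of range 0..{len(fl.results) - 1}"
        )
    r = fl.results[position]
    if r.match_type is not MatchType.SUGGESTION_PENDING:
        raise SuggestionStateError(
            f"result at position {position} is {r.match_type.label!r}, "
            "not awaiting a decision"
        )
    if gene_id not in {s.gene_id for s in r.suggestions}:
        raise SuggestionStateError(
            f"gene {gene_id} is not among the suggestions for {r.term!r}"
        )
    accepted = replace(r, match_type=MatchType.SUGGESTION_ACCEPTED, gene_id=gene_id)
    results = fl.results[:position] + (accepted,) + fl.results[position + 1:]
    return FinalList(tax_id=fl.tax_id, results=results)
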