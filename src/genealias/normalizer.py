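"""Term normalization: the variant forms a searched gene name is tried under.

Obsolete or colloquial gene names differ from official NCBI symbols mostly in
trivial ways — letter case, hyphens/underscores/spaces, and Greek letters
written as Unicode characters ("TGF-β1") where the official symbol uses the
Latin initial ("TGFB1") or, in many synonyms, the spelled-out name ("TGFBETA").
This module generates the deterministic, ordered set of spellings a term is
matched under, plus the canonical key used for symbol-table lookups.

Greek characters are *replaced*, never deleted: dropping β from "TGF-β1" would
yield "TGF1", which names nothing, whereas substitution yields "TGFB1".
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InvalidTermError

# Greek letters that actually occur in gene nomenclature. Each maps to its
# Latin initial and its spelled-out name; other Greek letters pass through.
_GREEK_BASE = {
    "α": ("A", "ALPHA"),
    "β": ("B", "BETA"),
    "γ": ("G", "GAMMA"),
    "δ": ("D", "DELTA"),
    "ε": ("E", "EPSILON"),
    "κ": ("K", "KAPPA"),
    "λ": ("L", "LAMBDA"),
}

_GREEK_INITIAL: dict[str, str] = {}
_GREEK_NAME: dict[str, str] = {}
for _lo, (_ini, _name) in _GREEK_BASE.items():
    for _ch in (_lo, _lo.upper()):
        _GREEK_INITIAL[_ch] = _ini
        _GREEK_NAME[_ch] = _name

_SEPARATORS = re.compile(r"[-_\s]+")

# (strip_separators, greek_mode) applied to the uppercased term, in emission
# order: case-only, separator removal, Greek substitutions, then combinations.
_TRANSFORMS = (
    (False, None),
    (True, None),
    (False, "initial"),
    (False, "name"),
    (True, "initial"),
    (True, "name"),
)


@dataclass(frozen=True)
class TermVariants:
    """A searched term and its ordered, de-duplicated normalized spellings.

    ``variants[0]`` is always the (whitespace-trimmed) original.
    """

    original: str
    variants: tuple[str, ...]

    def __post_init__(self):
        if not self.variants or self.variants[0] != self.original:
            raise ValueError("variants must start with the original term")
        if any(not v for v in self.variants):
            raise ValueError("variants must not contain empty strings")


def _substitute_greek(text: str, mode: str) -> str:
    table = _GREEK_INITIAL if mode == "initial" else _GREEK_NAME
    return "".join(table.get(ch, ch) for ch in text)


def variants(term: str) -> TermVariants:
    """Generate the ordered variant spellings of *term*.

    Emitted in order: the original; the uppercased form; the form with
    hyphens/underscores/whitespace removed; Greek→initial; Greek→name; and
    every combination of those transforms. Transformed variants are
    uppercase. Duplicates are dropped keeping the first occurrence, so an
    already-canonical term like "CRP" yields just itself.

    Raises :class:`InvalidTermError` on an empty or whitespace-only term.
    """
    trimmed = term.strip()
    if not trimmed:
        raise InvalidTermError(f"invalid search term: {term!r}")
    out: list[str] = [trimmed]
    seen = {trimmed}
    for strip_sep, greek in _TRANSFORMS:
        v = trimmed.upper()
        if greek is not None:
            v = _substitute_greek(v, greek)
        if strip_sep:
            v = _SEPARATORS.sub("", v)
        if v and v not in seen:
            seen.add(v)
            out.append(v)
    return TermVariants(original=trimmed, variants=tuple(out))


def canonical_key(symbol: str) -> str:
    """Case- and separator-insensitive lookup key for an official symbol.

    Uppercases and strips hyphens, underscores and internal whitespace.
    Idempotent; Greek characters are left alone (official NCBI symbols are
    ASCII, and variant generation handles Greek on the query side).
    """
    if not symbol:
        raise InvalidTermError("empty symbol has no canonical key")
    return _SEPARATORS.sub("", symbol).upper()
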