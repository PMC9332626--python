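"""Exception hierarchy.

Everything raised on purpose derives from :class:`GeneAliasError` so callers
(and the CLI) can catch one base class.
"""


class GeneAliasError(Exception):
    """Base class for all errors raised by this package."""


class InvalidTermError(GeneAliasError, ValueError):
    """A search term is empty or whitespace-only."""


class GeneInfoParseError(GeneAliasError):
    """A gene_info-dialect row could not be parsed.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class IndexBuildError(GeneAliasError, ValueError):
    """Record collection violates an index precondition (mixed taxa,
    duplicate official symbols)."""


class UnknownNamespaceError(GeneAliasError, ValueError):
    """Requested identifier namespace is not present in the index."""

    def __init__(self, namespace: str, available):
        self.namespace = namespace
        self.available = tuple(sorted(available))
        super().__init__(
            f"unknown namespace {namespace!r}; available: {', '.join(self.available)}"
        )


class UnknownColumnError(GeneAliasError, ValueError):
    """Requested table column specifier is not recognised."""


class SuggestionStateError(GeneAliasError, ValueError):
    """accept_suggestion called on a result that is not awaiting a decision,
    or with a gene that was not offered."""
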