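"""Exception hierarchy.

Every user-facing failure mode raises a named subclass of :class:`NetpharmError`
so callers (and the CLI) can distinguish validation problems from compute
failures.
"""


class NetpharmError(Exception):
    """Base class for all package errors."""


class ValidationError(NetpharmError):
    """Invalid input, parameter out of range, or malformed configuration."""


class SymbolError(ValidationError):
    """A token normalizes to an empty gene symbol."""


class LabelClashError(ValidationError):
    """Two inputs carry the same label where unique labels are required."""


class MalformedRowError(ValidationError):
    """A tabular input row could not be parsed; carries the line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class MissingColumnError(ValidationError):
    """A required column is absent from a tabular input."""


class SeedsNotInNetworkError(NetpharmError):
    """No seed gene of the query set is present in the association network."""


class EmptyGraphError(NetpharmError):
    """An operation that needs at least one node received an empty graph."""


class CliqueLimitExceededError(NetpharmError):
    """Maximal-clique enumeration aborted after exceeding the configured cap."""


class EmptyQueryError(NetpharmError):
    """The query gene set has no member inside the enrichment universe."""


class UnsatisfiableSpecError(ValidationError):
    """A synthetic-fixture specification cannot be realized; names the constraint."""
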