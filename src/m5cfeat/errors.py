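"""Exception hierarchy shared across the pipeline.

Precondition violations on arguments raise plain :class:`ValueError`;
the classes here mark data/format problems that a caller may want to
handle distinctly (the CLI maps them to exit code 3).
"""


class M5CError(Exception):
    """Base class for data- and format-level errors."""


class FormatError(M5CError):
    """A file does not conform to its expected text dialect."""


class AlphabetError(M5CError):
    """A sequence contains characters outside {A, C, G, U} (after T→U)."""


class ValidationError(M5CError):
    """Structurally well-formed input violates a semantic contract."""


class BoundaryError(M5CError):
    """A window cannot be extracted because flanking sequence is missing."""


class KmerLookupError(M5CError, KeyError):
    """A k-mer is absent from an embedding table under the 'error' policy."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)
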