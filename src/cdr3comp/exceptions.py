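"""Exception hierarchy shared across the package.

Everything derives from :class:`Cdr3CompError` so callers can catch one
base class; most also derive from ``ValueError`` because they signal bad
inputs rather than internal faults.
"""


class Cdr3CompError(Exception):
    """Base class for all package errors."""


class AlphabetError(Cdr3CompError, ValueError):
    """A sequence contains a letter outside the accepted alphabet."""

    def __init__(self, letter: str, position: int, context: str = ""):
        self.letter = letter
        self.position = position
        where = f" in {context}" if context else ""
        super().__init__(
            f"non-standard letter {letter!r} at position {position}{where}"
        )


class ValidationError(Cdr3CompError, ValueError):
    """An input value violates a documented invariant."""


class DegenerateSplitError(Cdr3CompError, ValueError):
    """All complementarity scores identical: no median split exists."""


class UndefinedStatisticError(Cdr3CompError, ValueError):
    """A statistic is undefined for the given data (no events, zero variance...)."""


class JoinError(Cdr3CompError, ValueError):
    """Case-id intersection between two inputs is empty or too small."""
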