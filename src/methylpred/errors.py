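"""Exception hierarchy shared across the package.

Every error raised by methylpred derives from :class:`MethylpredError`, so
callers (and the command-line layer) can map failures to categories without
string matching.
"""


class MethylpredError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SequenceLengthError(MethylpredError, ValueError):
    """Sequence too short (or empty signal) for the requested operation."""

    exit_code = 3


class AlphabetError(MethylpredError, ValueError):
    """Sequence contains a character outside {A, C, G, T}.

    Carries the offending character and its 0-based position.
    """

    exit_code = 3

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        prefix = f"{context}: " if context else ""
        super().__init__(
            f"{prefix}disallowed character {char!r} at position {position} "
            "(alphabet is A/C/G/T)"
        )


class ConfigurationError(MethylpredError, ValueError):
    """Mutually inconsistent or out-of-range configuration values."""

    exit_code = 4


class DataError(MethylpredError, ValueError):
    """Invalid dataset content (empty input, degenerate labels, width mismatch...)."""

    exit_code = 5
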