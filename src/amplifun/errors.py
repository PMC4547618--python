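"""Exception hierarchy.

Every error raised by the library derives from :class:`AmplifunError`, so callers
(including the CLI) can distinguish data problems from programming errors.
"""


class AmplifunError(Exception):
    """Base class for all library errors."""


class ProfileError(AmplifunError):
    """Invalid abundance profile (negative values, duplicate features, ...)."""


class EmptyProfileError(ProfileError):
    """A profile with zero total mass where positive mass is required."""


class KindMismatchError(ProfileError):
    """Two profiles of different kinds (otu/organism/ko) were combined."""


class AlphabetError(AmplifunError):
    """A sequence contains a symbol outside the nucleotide alphabet."""

    def __init__(self, symbol: str, context: str | None = None):
        self.symbol = symbol
        where = f" in {context}" if context else ""
        super().__init__(f"invalid nucleotide symbol {symbol!r}{where}; "
                         "allowed: A, C, G, T, U, N (case-insensitive)")


class FormatError(AmplifunError):
    """Malformed external file; carries a line number when one is known."""

    def __init__(self, message: str, line: int | None = None, path=None):
        self.line = line
        self.path = path
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class DialectError(FormatError):
    """A tabular file whose header matches no accepted dialect."""


class MissingOrganismError(AmplifunError):
    """Organism identifiers inconsistent between reference inputs."""

    def __init__(self, message: str, organisms=()):
        self.organisms = tuple(organisms)
        super().__init__(message)


class MissingCopyNumberError(MissingOrganismError):
    """An organism with positive abundance has no 16S copy number."""


class NoMappedOtusError(AmplifunError):
    """No input mass could be assigned to any genome."""

    def __init__(self, message: str = "no OTU mapped to any reference genome"):
        self.fraction_unmapped = 1.0
        super().__init__(message)


class ZeroRankVarianceError(AmplifunError):
    """Rank correlation requested on a constant vector (undefined)."""


class NoNonzeroDifferencesError(AmplifunError):
    """Sign test requested but every paired difference is exactly zero."""
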