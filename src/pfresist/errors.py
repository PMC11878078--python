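"""Exception hierarchy.

Each error class carries a distinct process exit code so the CLI can
signal validation, referential, and coverage failures differently.
"""


class PfResistError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(PfResistError):
    """Malformed, inconsistent, or undefined input (validation failures)."""

    exit_code = 2


class ParseError(InputError):
    """A table file could not be parsed; the message names the offending line."""

    exit_code = 2


class ReferentialError(PfResistError):
    """An identifier points at an entity that does not exist."""

    exit_code = 3


class CoverageError(PfResistError):
    """An isolate x phage grid has duplicate or missing cells."""

    exit_code = 4


class NoGrowthError(PfResistError):
    """A control growth curve shows no growth, so no exponential window exists."""

    exit_code = 5


class InsufficientReplicationError(PfResistError):
    """Too few replicates for a significance call."""

    exit_code = 6


class AlignmentError(PfResistError):
    """A time window does not overlap the sampled time range."""

    exit_code = 6


class ChecksumError(PfResistError):
    """A packaged fixture does not match its recorded checksum."""

    exit_code = 7
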