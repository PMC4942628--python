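"""Exception hierarchy.

All package-specific errors derive from :class:`LypredError` so callers
(and the CLI) can distinguish validation problems from genuine bugs.
"""


class LypredError(Exception):
    """Base class for all errors raised by lypred."""


class FastaParseError(LypredError):
    """Malformed FASTA input (e.g. sequence data before the first '>')."""


class EmptyInputError(LypredError):
    """An input file contained no records."""


class SequenceValidationError(LypredError):
    """A sequence violates the residue-alphabet or length rules."""


class DegenerateScaleError(LypredError):
    """A property row is constant and cannot be variance-normalized."""


class SequenceTooShortError(LypredError):
    """Sequence too short for the requested encoder parameters."""


class AlignmentError(LypredError):
    """Records and labels cannot be aligned by identifier."""


class InsufficientDataError(LypredError):
    """A class has too few samples for the requested computation."""


class ConfigError(LypredError):
    """Inconsistent or invalid run configuration."""


class StratificationError(LypredError):
    """A cross-validation fold would lack one of the two classes."""


class InconsistencyError(LypredError):
    """No integer confusion counts reproduce the stated rates."""


class UndefinedROCError(LypredError):
    """ROC requested with only one class present."""


class SyntheticSpecError(LypredError):
    """Invalid synthetic dataset specification."""
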