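"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
ReconstructionError -> 3; fit-quality problems are flags on results,
never exceptions.
"""


class CtdosimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CtdosimError):
    """Invalid configuration, unknown enum value, or malformed input schema."""


class ValidationError(CtdosimError):
    """An argument violates an operation precondition."""


class FormatError(CtdosimError):
    """Input file is not in the expected format (e.g. not DICOM Part 10)."""


class ConsistencyError(CtdosimError):
    """Inputs that must agree do not (e.g. mixed patients in one file set)."""


class ReconstructionError(CtdosimError):
    """Dose reconstruction cannot proceed (missing parameter, no PDF, ...)."""


class ExtrapolationError(ReconstructionError):
    """A lookup fell outside the coefficient-table grid; extrapolation is
    never performed silently."""


class ElicitationError(CtdosimError):
    """No observations and no era default exist for a missing parameter."""
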