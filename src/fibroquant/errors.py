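"""Exception hierarchy shared across fibroquant modules.

All errors raised deliberately by the library derive from
:class:`FibroquantError`; anything else escaping the public API is a bug.
"""


class FibroquantError(Exception):
    """Base class for all fibroquant errors."""


class InputError(FibroquantError):
    """A file or argument could not be read or resolved."""


class UnsupportedFormatError(InputError):
    """An image is not decodable as 8-bit RGB."""


class SchemaError(InputError):
    """An annotation or table file violates the documented schema."""


class PreconditionError(FibroquantError):
    """An operation was called with arguments violating its contract."""


class EmptySelectionError(PreconditionError):
    """A polygon selection covers no pixel centers."""


class CalibrationError(FibroquantError):
    """Stain calibration could not be fit (e.g. too few reference pixels)."""


class QuantificationError(FibroquantError):
    """mIF could not be computed (e.g. empty evaluation region)."""


class GenerationError(FibroquantError):
    """A synthetic slide or cohort could not be generated as requested."""


class UndefinedStatisticError(FibroquantError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ParameterError(FibroquantError):
    """A simulation parameter is outside its feasible range."""
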