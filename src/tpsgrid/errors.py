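"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes: parameter/configuration
problems, data problems, and everything else.
"""


class TpsGridError(Exception):
    """Base class for all package errors."""


class ParameterError(TpsGridError, ValueError):
    """A parameter is non-finite, out of range, or inconsistent."""


class FormatError(TpsGridError, ValueError):
    """An input file does not match the expected dialect."""


class EmptySectionError(TpsGridError, ValueError):
    """A cell table contains no records."""


class UndefinedScoreError(TpsGridError, ValueError):
    """A TPS was requested over a scope with zero viable tumour cells."""


class InsufficientDataError(TpsGridError, ValueError):
    """Too few observations for the requested statistic or comparison."""


class StructuralError(TpsGridError, ValueError):
    """A case is missing a structurally required component (e.g. a primary)."""
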