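"""Exception types shared across the package."""


class PCCountError(Exception):
    """Base class for all package errors."""


class ParameterError(PCCountError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(PCCountError, ValueError):
    """An input file decodes but does not describe a usable image."""


class DegenerateImageError(PCCountError, ValueError):
    """The image admits no threshold (e.g. a constant field of view)."""


class DegenerateTrainingError(PCCountError, ValueError):
    """A training set is missing one of the two classes."""


class UndefinedMetricError(PCCountError, ZeroDivisionError):
    """A classification metric has a zero denominator."""


class GenerationError(PCCountError, RuntimeError):
    """Synthetic scene generation could not satisfy its constraints."""
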