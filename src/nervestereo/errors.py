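"""Exception types shared across the package."""


class NerveStereoError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NerveStereoError, ValueError):
    """A geometric or sampling parameter violates its precondition."""


class NoSolutionError(NerveStereoError, ValueError):
    """A calibration target is unreachable within the shape family."""


class DegenerateGeometryError(NerveStereoError, ValueError):
    """Input geometry is degenerate (e.g. all trace points coincide)."""


class NoPoreError(NerveStereoError, ValueError):
    """A restriction line was requested but the section has no pore."""


class NotFoundError(NerveStereoError, LookupError):
    """A requested label/structure is absent from the data."""


class InsufficientDataError(NerveStereoError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedEstimateError(NerveStereoError, ZeroDivisionError):
    """The estimator is undefined (e.g. no test point hit the target)."""
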