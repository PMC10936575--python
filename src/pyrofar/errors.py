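"""Exception hierarchy.

Every validation failure has its own class so callers (and the CLI) can
report a single-line diagnostic naming what went wrong, rather than
pattern-matching message strings.
"""


class PyrofarError(Exception):
    """Base class for all package errors."""


class EnsembleValidationError(PyrofarError):
    """An ensemble violates its invariants."""


class EnsembleTooSmallError(EnsembleValidationError):
    """Fewer than two fire sizes; density estimation is impossible."""


class NonPositiveSizeError(EnsembleValidationError):
    """A fire size is zero, negative, or non-finite."""


class NonNumericDataError(EnsembleValidationError):
    """The size column contains cells that do not parse as numbers."""


class DegenerateEnsembleError(PyrofarError):
    """All fire sizes identical: zero sample variance, no bandwidth."""


class BandwidthError(PyrofarError):
    """Bandwidth rule unknown, or explicit bandwidth not positive."""


class PercentileOutOfRangeError(PyrofarError):
    """Requested exceedance level is outside what the curve attains."""


class LevelNotAttainedError(PyrofarError):
    """A FAR level is never reached within the valid region of a curve."""


class SimulationError(PyrofarError):
    """Invalid simulator configuration or ignition."""
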