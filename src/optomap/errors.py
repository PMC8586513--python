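"""Exception hierarchy for the optical-mapping pipeline.

Every pipeline stage raises a subclass of :class:`OptomapError`, so callers
(and the CLI) can attribute failures to a stage and distinguish bad user
input (:class:`ValidationError`) from data that cannot support the requested
computation (:class:`DegenerateInputError`, :class:`NoTransientError`, ...).
"""


class OptomapError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(OptomapError, ValueError):
    """A parameter or input violates a documented precondition."""


class FormatError(OptomapError):
    """An input file is unreadable or not a supported grayscale TIFF."""


class DegenerateInputError(OptomapError):
    """Input data admits no meaningful answer (e.g. constant frame)."""


class DetectionError(OptomapError):
    """Transient landmark detection failed (with diagnostics in the message)."""


class NoTransientError(DetectionError):
    """No deflection above the noise floor was found in the analysis window."""


class DurationNotReachedError(DetectionError):
    """The trace never recovered to the requested percentage level."""


class TauNotReachedError(DetectionError):
    """The trace never decayed to the 1/e amplitude level."""


class MapError(OptomapError):
    """Too many pixels failed per-pixel analysis to form a usable map."""
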