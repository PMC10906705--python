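"""Exception hierarchy.

Every error raised by this package derives from :class:`AerosolWatchError`,
so callers can distinguish pipeline failures from programming errors.
"""


class AerosolWatchError(Exception):
    """Base class for all package errors."""


class FormatError(AerosolWatchError):
    """A file does not match the expected dialect (missing columns, bad header)."""


class ValidationError(AerosolWatchError):
    """Data violate an invariant of the data model (negative counts, bad spacing)."""


class VocabularyError(AerosolWatchError):
    """An event label is outside the closed annotation vocabulary."""


class WindowError(AerosolWatchError):
    """A requested time window does not fit inside the recording."""


class ParameterError(AerosolWatchError):
    """An analysis parameter violates its precondition (even kernel, tiny n_boot)."""


class ConfigurationError(AerosolWatchError):
    """Inconsistent configuration (e.g. a size channel straddling the cutoff)."""


class InferenceError(AerosolWatchError):
    """A statistical comparison cannot be performed (group too small, empty subgroup)."""


class ExtractionError(AerosolWatchError):
    """An event window cannot be extracted from the recording."""


class SamplingError(AerosolWatchError):
    """Null-reference sampling cannot satisfy its constraints."""


class DegenerateFitError(AerosolWatchError):
    """Mixture fit collapsed (e.g. no positive samples).

    Carries the degenerate fit on the ``fit`` attribute so callers can
    still inspect the normal-only parameters.
    """

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit
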