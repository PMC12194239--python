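"""Exception hierarchy shared across the pipeline stages."""


class UrchinDriftError(Exception):
    """Base class for all package errors."""


class ValidationError(UrchinDriftError, ValueError):
    """An in-memory object violates one of its invariants."""


class FormatError(UrchinDriftError, ValueError):
    """A file on disk does not conform to the expected layout."""


class ConfigurationError(UrchinDriftError, ValueError):
    """A run configuration is inconsistent or unsatisfiable."""


class DataError(UrchinDriftError, ValueError):
    """Tabular input contains values outside the declared level sets."""


class EmptySelectionError(UrchinDriftError, ValueError):
    """A filter (months, window, ...) selected no records."""


class OutOfDomainError(UrchinDriftError):
    """A query point left the spatial or temporal extent of a gridded field.

    Carries the last valid position so the caller can decide the particle's
    fate (e.g. mark it as having exited the model domain).
    """

    def __init__(self, message: str, last_position=None):
        super().__init__(message)
        self.last_position = last_position
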