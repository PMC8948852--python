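"""Exception hierarchy shared across the package."""


class KinaromError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KinaromError):
    """Input violates the expected schema (unknown joint, duplicate id, ...)."""


class StreamParseError(KinaromError):
    """A skeleton-stream file could not be parsed; names the offending line."""


class EmptyStreamError(KinaromError):
    """A stream or series has no usable content."""


class DomainError(KinaromError, ValueError):
    """A value is outside its documented domain (angle range, window parity, ...)."""


class DegenerateGeometryError(KinaromError):
    """Vectors too short or collinear for a meaningful angle."""


class FrameExcluded(KinaromError):
    """Signal: a frame cannot contribute a measurement (e.g. untracked joint).

    Carries a human-readable reason; callers that iterate over streams catch
    it and record the frame in the exclusion list instead of failing.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ConfigError(KinaromError):
    """Missing or inconsistent configuration (thresholds, band schemes, ...)."""


class IncompleteSheetError(KinaromError):
    """An assessment sheet is missing items or scores; lists the item ids."""

    def __init__(self, message: str, missing: list | None = None):
        super().__init__(message)
        self.missing = list(missing or [])
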