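"""Exception types shared across the package."""


class OcthrombusError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(OcthrombusError):
    """A required configuration key or parameter is missing or inconsistent."""


class FormatError(OcthrombusError):
    """Input data does not match the expected layout (shape, dtype, pages)."""


class AnalysisError(OcthrombusError):
    """An operation's preconditions are not met by the supplied data."""
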