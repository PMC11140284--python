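"""Exception types shared across the package."""


class VistrajError(Exception):
    """Base class for package errors."""


class ConfigError(VistrajError):
    """Invalid simulation or pipeline configuration."""


class EstimationError(VistrajError):
    """Model estimation failed (degenerate data, no converged start, ...)."""


class DataError(VistrajError):
    """Malformed or inconsistent input data."""
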