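"""Exception hierarchy shared across the package."""


class MetgainsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MetgainsError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ClassificationError(MetgainsError, ValueError):
    """Environment classification cannot proceed (too few distinct means)."""


class PedigreeError(MetgainsError, ValueError):
    """Malformed pedigree: unresolved ids or cycles."""


class GainsError(MetgainsError, ValueError):
    """Check-relative yield or gain regression cannot be computed."""


class ValidationError(MetgainsError, ValueError):
    """Input files violate the expected schema."""
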