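"""Exception taxonomy shared across the package."""


class IsoloadError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IsoloadError, ValueError):
    """A configuration block is inconsistent (e.g. min > max in a range)."""


class ParameterError(IsoloadError, ValueError):
    """A function argument is outside its documented domain."""


class DataError(IsoloadError, ValueError):
    """Input data violate a physical or structural precondition."""


class DegenerateInputError(IsoloadError, ValueError):
    """Input is structurally valid but too short/empty for the operation."""


class SamplingError(IsoloadError, ValueError):
    """A sampling rate is too low to represent the requested signal."""
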