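"""Exception types shared across the package."""


class LarvanetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LarvanetError):
    """A run or generator configuration is internally inconsistent."""


class OnLandError(LarvanetError):
    """A velocity lookup landed on a fully dry interpolation stencil."""


class DataError(LarvanetError):
    """Input records reference unknown sites/species or are malformed."""
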