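"""Exception types shared across the package."""


class EmegScanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmegScanError):
    """A parameter or configuration value is invalid."""


class GeometryError(EmegScanError):
    """A position violates the head geometry (outside/inside the wrong shell)."""


class InputError(EmegScanError):
    """Input data are malformed or insufficient for the requested operation."""
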