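"""Exception hierarchy used across the package."""


class WgksError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(WgksError, ValueError):
    """A parameter (k, cluster count, rate, ...) is outside its valid range."""


class InvalidInputError(WgksError, ValueError):
    """An input object (genome, matrix, alignment, file) violates a contract."""


class DegenerateInputError(WgksError, ValueError):
    """Input is structurally valid but the requested quantity is undefined
    for it (e.g. a zero-variance signature fed to a correlation)."""
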