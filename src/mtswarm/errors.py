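"""Exception hierarchy shared across the package."""


class MtswarmError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MtswarmError):
    """A configuration is structurally invalid (unknown keys, missing sections)."""


class ValidationError(MtswarmError, ValueError):
    """A value violates a documented precondition (negative rate, shape mismatch)."""


class IntegrationError(MtswarmError):
    """The ODE solver failed to converge or produced unphysical output."""


class RangeError(MtswarmError, ValueError):
    """A requested coordinate lies outside the available range."""
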