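"""Exception hierarchy shared across the package."""


class PdoImmuneError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PdoImmuneError, ValueError):
    """A file or table violates the expected on-disk format."""


class DomainError(PdoImmuneError, ValueError):
    """Inputs are well-formed but outside an operation's domain."""


class StateError(PdoImmuneError, RuntimeError):
    """An object is in the wrong state for the requested operation
    (e.g. log-transforming an already log-scale matrix)."""
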