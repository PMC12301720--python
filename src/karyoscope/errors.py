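"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code (see :mod:`karyoscope.cli`).
"""


class KaryoscopeError(Exception):
    """Base class for all package errors."""


class FormatError(KaryoscopeError):
    """A file does not conform to its documented dialect."""


class ValidationError(KaryoscopeError):
    """In-memory data violates a type invariant."""


class ConfigError(KaryoscopeError):
    """A configuration value is inconsistent or out of range."""
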