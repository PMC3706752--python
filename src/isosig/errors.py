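"""Exception hierarchy shared across the package.

ValidationError signals a malformed argument or configuration (CLI exit
code 2); DataError signals inconsistent or unusable input data (exit 3).
"""


class IsosigError(Exception):
    """Base class for package errors."""


class ValidationError(IsosigError, ValueError):
    """An argument, spec or configuration field is invalid."""


class DataError(IsosigError, ValueError):
    """Input data are inconsistent (missing annotation, NaNs, ...)."""
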