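"""Exception hierarchy shared across the package."""


class CardiogridError(Exception):
    """Base class for all package errors."""


class SchemaError(CardiogridError):
    """A table does not match the declared feature schema."""


class ParseError(CardiogridError):
    """A cell could not be parsed into its declared type."""


class ValidationError(CardiogridError):
    """Input violates an operation precondition."""


class CapabilityError(CardiogridError):
    """An optional backend is requested but its dependency is unavailable."""


class IOError_(CardiogridError):
    """A file could not be read or written."""
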