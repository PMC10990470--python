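"""Exception hierarchy shared across the package."""


class SweepscanError(Exception):
    """Base class for all package errors."""


class ValidationError(SweepscanError):
    """Invalid inputs or configuration detected before computation."""


class DataError(SweepscanError):
    """Malformed or inconsistent data encountered while computing."""
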