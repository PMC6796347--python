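"""Exception types shared across the package."""


class NrscoutError(Exception):
    """Base class for package errors."""


class InputError(NrscoutError):
    """Malformed or inconsistent user input (exit code 1 territory)."""


class ConfigError(NrscoutError):
    """Invalid configuration value."""


class AlignmentSizeError(NrscoutError):
    """Dynamic-programming matrix would exceed the configured cell cap."""


class DegenerateInputError(NrscoutError):
    """Input carries no usable signal (e.g. zero-variance matrix)."""


class IntegrityError(NrscoutError):
    """Provenance coordinates do not match the sequence they point into."""
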