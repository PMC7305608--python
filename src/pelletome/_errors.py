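"""Exception hierarchy shared across the package."""


class PelletomeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PelletomeError, ValueError):
    """A file could not be parsed as the expected tabular format."""


class ValidationError(PelletomeError, ValueError):
    """Parsed data violate a structural invariant of the data model."""


class PairingError(PelletomeError, ValueError):
    """Soluble/pellet pairing cannot be derived for any subject."""
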