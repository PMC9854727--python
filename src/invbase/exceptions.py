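"""Exception hierarchy for invbase."""


class InvBaseError(Exception):
    """Base class for all invbase errors."""


class ValidationError(InvBaseError, ValueError):
    """Input data or parameters violate a documented precondition."""


class FormatError(InvBaseError, ValueError):
    """A file is structurally malformed (missing dataset, bad header)."""


class UnsupportedFormatError(FormatError):
    """A file is well-formed but uses a feature this package does not read."""


class ConfigurationError(InvBaseError, ValueError):
    """A configuration object is internally inconsistent."""
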