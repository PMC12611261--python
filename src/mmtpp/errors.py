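"""Exception hierarchy.

``ValidationError`` covers malformed inputs and configs (CLI exit code 2);
everything else raised by the package is an ``MMTPPError`` (exit code 3).
"""


class MMTPPError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MMTPPError, ValueError):
    """Invalid input data or configuration."""


class TransformStateError(MMTPPError, RuntimeError):
    """A matrix operation was called out of the fixed preprocessing order."""
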