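"""Exception hierarchy.

``ConfigurationError`` covers problems a user can fix by changing flags,
column maps or config files; ``ValidationError`` covers malformed data
rows or inputs that violate a method's preconditions.
"""


class CytomrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CytomrError):
    """Bad or missing configuration (column maps, thresholds, LD files)."""


class ValidationError(CytomrError):
    """Input data violates an invariant or a method precondition."""
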