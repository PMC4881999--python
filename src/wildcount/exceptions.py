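"""Exception hierarchy for wildcount.

All errors raised by the library derive from :class:`WildcountError` so
callers can catch one base class; most also derive from the closest
builtin (``ValueError``/``IOError``) so idiomatic handling still works.
"""


class WildcountError(Exception):
    """Base class for all wildcount errors."""


class InvalidInputError(WildcountError, ValueError):
    """An input array or image violates a precondition."""


class InvalidParameterError(WildcountError, ValueError):
    """A scalar parameter is out of its valid range."""


class InvalidSpecError(WildcountError, ValueError):
    """A descriptor spec entry violates the rotation-invariance conditions."""


class InvalidConfigError(WildcountError, ValueError):
    """A configuration is internally inconsistent (e.g. blob larger than scene)."""


class InvalidModelError(WildcountError, ValueError):
    """A trained model does not match the requested feature configuration."""


class UndefinedStatisticError(WildcountError, ValueError):
    """A statistic is undefined for the given data (zero denominator)."""


class InsufficientDataError(WildcountError, ValueError):
    """Too few observations remain to compute the requested quantity."""


class FormatError(WildcountError, ValueError):
    """A file does not conform to the expected tabular format."""
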