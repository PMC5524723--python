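"""Exception hierarchy shared across the package.

Everything derives from :class:`AquaEnhanceError` so callers can catch the
package's failures with one clause; the concrete subclasses mirror the
contract categories used throughout (bad parameters, bad input data, values
outside a mathematical domain, degenerate inputs such as constant images,
and file I/O problems).
"""


class AquaEnhanceError(Exception):
    """Base class for all errors raised by aquaenhance."""


class InvalidParameterError(AquaEnhanceError, ValueError):
    """A configuration or algorithm parameter violates its contract."""


class InvalidInputError(AquaEnhanceError, ValueError):
    """Input data (an image, a vector) violates a precondition."""


class DomainError(AquaEnhanceError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateInputError(AquaEnhanceError, ValueError):
    """Input is formally valid but degenerate (e.g. a constant image)."""


class ImageIOError(AquaEnhanceError, OSError):
    """Reading or writing an image file failed."""
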