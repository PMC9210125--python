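"""Exception hierarchy.

All package errors derive from :class:`MedSRNetError`; most also derive
from :class:`ValueError` so that generic callers can catch them naturally.
"""


class MedSRNetError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(MedSRNetError, ValueError):
    """Invalid or unknown configuration value."""


class SpecError(MedSRNetError, ValueError):
    """An architecture or phantom specification violates its invariants."""


class DimensionError(MedSRNetError, ValueError):
    """Image or feature-map dimensions violate an operation's contract."""


class GeometryError(MedSRNetError, ValueError):
    """No valid transposed-convolution padding solution exists."""


class DomainError(MedSRNetError, ValueError):
    """A numeric input lies outside its mathematical domain."""


class PairingError(MedSRNetError, ValueError):
    """SR/HR files could not be matched one-to-one."""


class FormatError(MedSRNetError, ValueError):
    """Unsupported image file format."""


class NumericalError(MedSRNetError, ArithmeticError):
    """A loss or gradient became non-finite during optimisation."""
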