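"""Exception hierarchy shared across the package."""


class IceclockError(Exception):
    """Base class for all package-specific errors."""


class DomainError(IceclockError):
    """A query point lies outside (or too close to the edge of) a gridded field."""


class StagnationError(IceclockError):
    """Flow speed fell below the stagnation threshold; transit time diverges."""


class ProfileRangeError(IceclockError):
    """A depth query lies outside the modeled marine-ice column."""


class EmptyStackError(IceclockError):
    """An age-depth profile was requested from an empty layer stack."""


class MalformedRecordError(IceclockError):
    """A SAM record's CIGAR and sequence are inconsistent."""


class UndefinedRateError(IceclockError):
    """A rate is undefined (zero denominator)."""


class SaturationError(IceclockError):
    """Jukes-Cantor correction undefined: observed proportion >= 3/4."""


class FrameError(IceclockError):
    """A coding sequence contains an internal stop codon."""


class ConfigurationError(IceclockError):
    """Invalid configuration (unknown scenario/field kind, bad parameters)."""
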