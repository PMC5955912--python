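"""Exception hierarchy."""


class OLRKitError(Exception):
    """Base class for olrkit errors."""


class ArgumentError(OLRKitError, ValueError):
    """Invalid argument value for an operation."""


class GridFormatError(OLRKitError, ValueError):
    """Projection-LUT node measurements do not form a valid monotone grid."""


class OutOfRangeError(OLRKitError, ValueError):
    """Query outside the domain covered by a lookup table or trace."""


class ConfigError(OLRKitError, ValueError):
    """Invalid run configuration; message carries the offending key path."""


class DataError(OLRKitError, ValueError):
    """Dataset does not satisfy the preconditions of an analysis step."""
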