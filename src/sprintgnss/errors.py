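"""Exception hierarchy shared across the pipeline.

ParseError / ValidationError map to CLI exit code 2 (bad input),
DataError to exit code 3 (data that parses but cannot be processed).
"""


class SprintGnssError(Exception):
    """Base class for all package errors."""


class ParseError(SprintGnssError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(SprintGnssError):
    """Parsed data violates a structural invariant (e.g. non-monotonic time)."""


class ConfigError(SprintGnssError):
    """Missing or inconsistent configuration (e.g. undeclared IMU unit)."""


class DataError(SprintGnssError):
    """Valid data that cannot support the requested computation
    (e.g. a GNSS gap too long to bridge, or 400 m never reached)."""
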