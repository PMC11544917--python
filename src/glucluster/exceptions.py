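"""Exception hierarchy for glucluster."""


class GluclusterError(Exception):
    """Base class for all glucluster errors."""


class ConfigurationError(GluclusterError):
    """Invalid configuration value (bad shape id, bad proportions, bad ranges)."""


class DataError(GluclusterError):
    """Malformed input data (unsorted timestamps, shape mismatches)."""


class PreconditionError(GluclusterError):
    """An operation was called on input violating its documented precondition."""


class BoundaryGapError(GluclusterError):
    """A 1-2 point gap touches the segment boundary, so no two-sided mean exists.

    Segments raising this are rejected rather than extrapolated.
    """
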