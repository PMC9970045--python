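"""Exception hierarchy with documented CLI exit codes.

0 = success, 2 = schema/config, 3 = data, 4 = numeric/degenerate.
"""


class StainRefError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(StainRefError):
    """Malformed manifest, config, or artifact structure."""

    exit_code = 2


class DataError(StainRefError):
    """Input data unusable (missing file, wrong depth, no tissue...)."""

    exit_code = 3


class NumericError(StainRefError):
    """Degenerate numerics (constant samples, zero-mass histogram...)."""

    exit_code = 4


class InsufficientTissueError(DataError):
    """Tissue mask retained too few pixels for stain estimation."""


class DegenerateRangeError(NumericError):
    """Samples span a zero-width range; no histogram can be binned."""


class DegenerateHistogramError(NumericError):
    """All raw bin counts equal; min-max scaling is undefined."""


class ZeroMassError(NumericError):
    """Histogram carries no mass; distances/CDFs are undefined."""
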