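"""Exception hierarchy.

The CLI maps these onto exit codes: configuration problems -> 2,
data problems -> 3, statistical degeneracy -> 4.
"""


class WmhTractError(Exception):
    """Base class for all package errors."""


class ConfigError(WmhTractError):
    """Invalid configuration value or missing configuration field."""


class DataError(WmhTractError):
    """Malformed, missing, or mutually inconsistent input data."""


class GridMismatchError(DataError):
    """Two volumes that must share a voxel grid / affine do not."""


class SizingError(ConfigError):
    """A requested grid is too small for the geometry it must hold."""


class DegenerateError(WmhTractError):
    """A statistical computation is degenerate (zero variance, identical
    points, insufficient observations)."""
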