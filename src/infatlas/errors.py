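"""Exception hierarchy for infatlas.

All errors derive from :class:`InfatlasError` so callers can catch the
package's failures with a single except clause; the concrete subclasses
mirror the failure modes of the pipeline stages (I/O, geometry, numerics).
"""


class InfatlasError(Exception):
    """Base class for all infatlas errors."""


class VolumeFormatError(InfatlasError):
    """Unreadable, truncated, or wrongly-dimensioned volume file."""


class SpaceError(InfatlasError):
    """Operands live on different or incompatible voxel grids."""


class ParameterError(InfatlasError, ValueError):
    """An argument is outside its documented domain."""


class MaskingError(InfatlasError):
    """Brain masking produced an empty or degenerate mask."""


class DegenerateInputError(InfatlasError):
    """Input lacks the structure an algorithm requires (e.g. too few
    distinct intensities for the requested number of classes)."""


class SingularSystemError(InfatlasError):
    """A linear system (e.g. the thin-plate-spline matrix) is singular,
    typically because control points are collinear or coplanar."""


class DivergenceError(InfatlasError):
    """A registration produced implausibly large displacements."""


class InversionError(InfatlasError):
    """Fixed-point field inversion failed to converge.

    Carries the residual (in voxels) that was reached.
    """

    def __init__(self, msg: str, residual_voxels: float | None = None):
        super().__init__(msg)
        self.residual_voxels = residual_voxels


class PairingError(InfatlasError):
    """A subject is missing from one of two groups that must be paired."""


class ConfigError(InfatlasError):
    """A run configuration violates its schema; message names the field."""
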