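"""Exception hierarchy.

Every error the library raises derives from :class:`ConngradError`, so callers
can catch one type at a pipeline boundary while tests assert on the precise
subclass.  Errors that concern particular voxels carry their ids.
"""

from __future__ import annotations


class ConngradError(Exception):
    """Base class for all conngrad errors."""


class InvalidSpecError(ConngradError):
    """A declarative specification (zone spec, labeling scheme, config) is malformed."""


class InvalidParameterError(ConngradError):
    """A numeric parameter is outside its documented domain."""


class InvalidStateError(ConngradError):
    """An operation was called on an object missing required state."""


class FlaggedVoxelError(ConngradError):
    """Voxels violate a precondition (e.g. zero variance); caller chooses drop or abort."""

    def __init__(self, message: str, voxel_ids):
        super().__init__(f"{message}: voxels {list(voxel_ids)}")
        self.voxel_ids = list(voxel_ids)


class DegenerateRowError(ConngradError):
    """A matrix row is degenerate (all-zero) for the requested operation."""

    def __init__(self, message: str, rows):
        super().__init__(f"{message}: rows {list(rows)}")
        self.rows = list(rows)


class DomainError(ConngradError):
    """Input values outside the mathematical domain (e.g. |r| >= 1 for atanh)."""


class ShapeMismatchError(ConngradError):
    """Operands do not align in shape or indexing."""


class GraphConnectivityError(ConngradError):
    """The affinity graph is disconnected; inspect sparsification settings."""


class EmptyRegionError(ConngradError):
    """A region/submask required to be nonempty is empty."""


class ParseError(ConngradError):
    """A file could not be parsed; message carries location context."""
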