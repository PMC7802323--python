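"""Exception hierarchy.

Each orchestration-level failure class maps to a distinct CLI exit code
(see :mod:`cellmech.cli`).
"""


class CellMechError(Exception):
    """Base class for all package errors."""


class ConfigError(CellMechError):
    """Invalid run configuration (schema violation, inconsistent blocks)."""


class MissingInputError(CellMechError):
    """A declared input file does not exist or lacks required metadata."""


class StageError(CellMechError):
    """A pipeline stage failed during execution."""


class MaskError(CellMechError):
    """A binary mask is empty, multi-component, or otherwise unusable."""


class GridFitError(CellMechError):
    """Pillar lattice reconstruction failed (wrong pitch/lattice type)."""


class TrackingError(CellMechError):
    """Pillar or cell tracking failed (too many unassigned detections)."""


class NoReferencePillarsError(CellMechError):
    """No cell-free pillars available; stage drift cannot be corrected."""
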