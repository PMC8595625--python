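"""Exception hierarchy shared across the package."""


class HelixnetError(Exception):
    """Base class for all package errors."""


class FormatError(HelixnetError):
    """A file could not be parsed in its declared format."""


class EmptyStructureError(HelixnetError):
    """A structure source contained no protein atoms."""


class TopologyError(HelixnetError):
    """Trajectory frames do not match the topology (atom count/order)."""


class InsertionCodeError(FormatError):
    """Residue insertion codes are present; author numbering would be ambiguous."""


class OutOfRangeError(HelixnetError):
    """A residue or generic-number lookup fell outside a defined segment range."""


class MissingPivotError(HelixnetError):
    """A pivot split was requested for a segment without a valid pivot."""


class ResidueLookupError(HelixnetError):
    """A residue could not be found in a structure."""


class NoCBetaError(HelixnetError):
    """Alanine truncation requested for a residue without a C-beta (Gly) or with a
    backbone-fused side chain (Pro)."""


class SelectionError(HelixnetError):
    """An atom selection was empty or inconsistent between structures."""


class UnderdeterminedFitError(SelectionError):
    """Fewer than three atoms selected for a rigid-body superposition."""


class IncompleteBackboneError(SelectionError):
    """A backbone atom required by the endpoint rule is missing."""


class DegenerateVectorError(HelixnetError):
    """A helix vector has (numerically) zero length."""


class InsufficientFramesError(HelixnetError):
    """An operation needs more trajectory frames than were supplied."""


class ParameterError(HelixnetError):
    """Missing or invalid per-atom parameters or numeric settings."""


class GeometryError(HelixnetError):
    """Atoms overlap or a generated placement clashes."""


class MatrixAlignmentError(HelixnetError):
    """Energy matrices do not share a residue universe or mask."""


class TypingError(HelixnetError):
    """No donor/acceptor or charged-group typing available for a residue."""


class ConfigError(HelixnetError):
    """Pipeline configuration is invalid; message carries the field path."""


class PlotError(HelixnetError):
    """Nothing to plot, or rendering inputs are degenerate."""
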