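"""Exception hierarchy."""


class ShapecloudError(Exception):
    """Base class for all package errors."""


class MoleculeParseError(ShapecloudError):
    """A structure file could not be parsed."""


class UnknownElementError(ShapecloudError):
    """An element symbol is missing from the radius table."""


class DegenerateSurfaceError(ShapecloudError):
    """Surface generation produced no points (all dots buried)."""


class DegenerateGeometryError(ShapecloudError):
    """Point sets too degenerate for a rigid fit (e.g. collinear)."""


class ContractError(ShapecloudError):
    """An operation was called outside its contract."""


class AlignmentFailureError(ShapecloudError):
    """No voxel size of the sweep produced a usable alignment."""
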