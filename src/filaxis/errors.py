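"""Exception hierarchy for filaxis."""


class FilaxisError(Exception):
    """Base class for all filaxis errors."""


class FormatError(FilaxisError):
    """A coordinate file could not be parsed or violates the format."""


class StructureError(FilaxisError):
    """A structure model violates an invariant (empty, duplicate ids, ...)."""


class SelectionError(FilaxisError):
    """A residue selection is malformed or resolves to nothing."""


class EnsembleError(FilaxisError):
    """A conformer ensemble cannot be built (too few members, empty core)."""


class GeometryError(FilaxisError):
    """Degenerate geometry: too few atoms, collinear points, mismatched sets."""


class NoRotationError(GeometryError):
    """Axis direction requested from an identity (no-rotation) screw axis."""


class ContactError(FilaxisError):
    """Contact analysis failed (unknown element, empty molecule, ...)."""


class GraftError(FilaxisError):
    """Rigid-body grafting or hybrid-filament construction failed."""
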