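"""Exception hierarchy used across the package."""


class DynophoreError(Exception):
    """Base class for all domain errors raised by this package."""


class ParseError(DynophoreError):
    """A structure or trajectory file could not be parsed."""


class ShapeError(DynophoreError):
    """Coordinate/atom-count mismatch between a frame and its topology."""


class SelectionError(DynophoreError):
    """A selection expression is invalid or refers to missing atoms."""


class GeometryError(DynophoreError):
    """A geometric operation received degenerate input."""


class PerceptionError(DynophoreError):
    """Feature perception could not run on the given atoms."""


class FeasibilityError(DynophoreError):
    """A synthetic interaction schedule demands contradictory geometry."""
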