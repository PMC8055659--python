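"""Exception hierarchy for mifspat."""


class MifspatError(Exception):
    """Base class for all mifspat errors."""


class CellTableFormatError(MifspatError):
    """A cell table file violates the canonical dialect (e.g. missing column)."""


class ValidationError(MifspatError):
    """A frame or record violates an invariant (duplicate ids, out-of-bounds coordinates, ...)."""


class MergeError(MifspatError):
    """Coordinate-based marker merge cannot proceed."""


class MergeAmbiguityError(MergeError):
    """Two cells in one input table collide within the merge tolerance."""


class ParameterError(MifspatError):
    """An operation received an out-of-range parameter."""
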