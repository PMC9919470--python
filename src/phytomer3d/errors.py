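"""Exception and warning types shared across the package."""


class GeometryError(ValueError):
    """Degenerate or invalid geometry (zero-length axis, collinear girth, ...)."""


class DigitizerFormatError(ValueError):
    """A digitizer file violates the documented dialect (e.g. the 3n+1 rule)."""


class InvalidCountError(ValueError):
    """A structural count (phytomers, tillers, nodes) is out of range."""


class TemplateLookupError(KeyError):
    """A template reference could not be resolved in the database."""


class DegenerateGeometryWarning(UserWarning):
    """Geometry is technically valid but degenerate (zero distances, flat hulls)."""


class SpikeLayerWarning(UserWarning):
    """No spike geometry present; a fallback layer definition was used."""


class ClassificationWarning(UserWarning):
    """A phytomer classification fell back to a non-canonical case."""


class SimilarityWarning(UserWarning):
    """A parameter was dropped from similarity scoring (zero variance)."""


class TipMismatchWarning(UserWarning):
    """Leaf surface tip and vein-trace tip disagree beyond tolerance."""
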