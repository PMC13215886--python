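"""Exception hierarchy for contour processing and STV generation."""


class ScartError(Exception):
    """Base class for all domain errors raised by this package."""


class DegenerateContourError(ScartError):
    """Contour has too few vertices, zero area, or is otherwise unusable."""


class NonSimpleContourError(ScartError):
    """Contour is self-intersecting; such input is rejected, not repaired."""


class OriginOutsideError(ScartError):
    """A polar origin or ray origin does not lie strictly inside the polygon."""


class InvalidPolarError(ScartError):
    """A polar contour violates its invariants (non-positive radius, bad grid)."""


class UnsupportedDoseError(ScartError):
    """Dose combination outside the tabulated shrink-policy range."""


class InvalidGapError(ScartError):
    """Superior-inferior gap outside the allowed 5-15 mm band."""


class InvalidWidthError(ScartError):
    """Non-positive ring width."""


class StvEmptyError(ScartError):
    """All STV slices were removed; the tumor is too small for SCART at this dose."""


class InvalidPhantomError(ScartError):
    """Phantom parameters produce an impossible or degenerate geometry."""


class UnsupportedGeometryError(ScartError):
    """Structure-set contour with a geometric type other than CLOSED_PLANAR."""


class MissingSpacingError(ScartError):
    """Single-slice structure with no declared slice spacing."""
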