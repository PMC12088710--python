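"""Exception hierarchy for octquant."""


class OctQuantError(Exception):
    """Base class for all octquant errors."""


class NoLumenError(OctQuantError):
    """Raised when a frame contains no lumen pixels."""


class OriginOutOfBoundsError(OctQuantError):
    """Ray-cast origin lies outside the frame."""


class SpecInfeasibleError(OctQuantError):
    """Phantom specification cannot be rendered inside the frame."""


class GeometryMismatchError(OctQuantError):
    """Frames with incompatible pixel geometry were combined."""


class ZeroArcError(OctQuantError):
    """Fibrous cap ratio requested for a zero-degree arc."""


class UndefinedScoreError(OctQuantError):
    """Correspondence score undefined (both arcs are zero)."""


class UndefinedMetricError(OctQuantError):
    """A binary performance metric has a zero denominator."""


class DegenerateTableError(OctQuantError):
    """Cohen's kappa undefined (expected agreement equals 1)."""


class DomainError(OctQuantError):
    """Argument outside its mathematical domain."""


class TooFewPairsError(OctQuantError):
    """Not enough paired measurements for the requested statistic."""


class EmptySetError(OctQuantError):
    """Aggregation requested over an empty record set."""


class IndexMismatchError(OctQuantError):
    """Observer tables do not share the same frame index set."""


class LengthMismatchError(OctQuantError):
    """Paired value vectors differ in length."""


class FormatError(OctQuantError):
    """Mask file is not in a supported format."""


class UnknownLabelError(OctQuantError):
    """Mask contains a label code outside the schema."""


class MissingSpacingError(OctQuantError):
    """Pixel spacing could not be resolved, or is anisotropic."""
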