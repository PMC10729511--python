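"""Exception hierarchy for the ramanpat package."""


class RamanPatError(Exception):
    """Base class for all package errors."""


class FormatError(RamanPatError):
    """A file could not be parsed (ragged rows, missing labels, bad header)."""


class ValidationError(RamanPatError):
    """Data violate a structural invariant (monotonicity, shapes, units)."""


class ParameterError(RamanPatError):
    """An operation was called with illegal parameters."""


class RangeError(RamanPatError):
    """A requested grid or timepoint lies outside the available data."""


class AlignmentError(RamanPatError):
    """Reference timepoints could not be matched to any spectrum."""


class NormalizationError(RamanPatError):
    """Anchor-peak normalization found a non-positive window maximum."""


class DegenerateFitError(RamanPatError):
    """A least-squares fit collapsed (scale factor ~ 0, zero-variance y)."""


class RankError(RamanPatError):
    """More components requested than the data can support."""


class UnitMismatchError(RamanPatError):
    """Model and reference data disagree on analyte units."""
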