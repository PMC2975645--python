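"""Exception hierarchy for the nirquant pipeline."""


class NirquantError(Exception):
    """Base class for all nirquant errors."""


class ValidationError(NirquantError):
    """An input violates a documented invariant (negative intensity, bad mask, ...)."""


class ShapeMismatchError(ValidationError):
    """Two arrays that must share a shape do not."""


class UnsupportedFormatError(NirquantError):
    """A file is not a format the pipeline reads (e.g. RGB TIFF)."""


class GeometryError(NirquantError):
    """Phantom geometry is infeasible (region outside body/image, no node placement)."""


class EmptyRegionError(NirquantError):
    """A statistic was requested over an empty pixel set."""


class NormalizationError(NirquantError):
    """Hip normalization cannot proceed (zero hip level)."""


class ConfigurationError(NirquantError):
    """A required region or input (hip_ref, control image) is missing."""


class DetectionError(NirquantError):
    """A seeded ROI could not be matched to any detected component."""


class AnnulusError(NirquantError):
    """A background annulus came out empty after exclusions."""


class DegenerateBackgroundError(NirquantError):
    """The background annulus has zero pixel variance in noise_sd mode."""
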