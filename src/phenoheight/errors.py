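"""Exception hierarchy for the phenoheight pipeline."""


class PhenoheightError(Exception):
    """Base class for all phenoheight errors."""


class InvalidDesignError(PhenoheightError):
    """Field design is inconsistent (empty factor lists, bad dimensions)."""


class GeometryError(PhenoheightError):
    """Plot boundary geometry is invalid (overlaps, duplicate positions)."""


class GeoreferenceError(PhenoheightError):
    """Raster and vector georeferences are incompatible."""


class ResolutionError(PhenoheightError):
    """Raster resolution too coarse for the requested operation."""


class EmptyPlotError(PhenoheightError):
    """No valid pixels fall inside a plot boundary."""


class EmptyBinError(PhenoheightError):
    """A bin contains no valid pixels."""


class ConfigurationError(PhenoheightError):
    """Parameters are inconsistent with the method's contract."""


class InsufficientDataError(PhenoheightError):
    """Too few observations for the requested statistic or fit."""


class DomainError(PhenoheightError):
    """Evaluation requested outside a fitted curve's time domain."""


class SamplingError(PhenoheightError):
    """A resampling request exceeds the available units."""


class AliasingError(PhenoheightError):
    """Factorial model cannot be estimated because design cells are missing."""


class ZeroVarianceError(PhenoheightError):
    """A correlation-based statistic is undefined for a constant series."""
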