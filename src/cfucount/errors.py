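"""Exception hierarchy for the colony-counting pipeline.

Every stage raises a subclass of :class:`CFUError` so the CLI can surface
the failing stage with a remediation hint and a nonzero exit code.
"""

from __future__ import annotations


class CFUError(Exception):
    """Base class for all pipeline errors."""

    hint: str = ""


class ImageFormatError(CFUError):
    """Input image is not an 8-bit RGB raster."""


class ImageReadError(CFUError, OSError):
    """Input image file is missing or cannot be decoded."""


class ParameterError(CFUError, ValueError):
    """A parameter violates its contract (e.g., even median kernel)."""


class ROIDetectionError(CFUError):
    """No circular dish structure could be found."""

    hint = "pass an explicit region of interest via --roi cx,cy,r"


class SeedBackgroundError(CFUError):
    """A flood fill from a seed point grew past the colony-area cap."""

    hint = "the seed point appears to lie on background; pick a new seed"


class NoPeakError(CFUError):
    """A histogram contains no positive mass to locate a peak in."""


class ThresholdSearchError(CFUError):
    """No (s, C) pair satisfied all histogram criteria.

    Carries the best partial assessment seen, for diagnostics.
    """

    hint = "check the seed points and consider widening the search grids"

    def __init__(self, message: str, best_partial=None):
        super().__init__(message)
        self.best_partial = best_partial


class DegenerateContourError(CFUError):
    """A contour has too few boundary points for shape fitting."""


class PipelineError(CFUError):
    """A cross-stage contract failed (e.g., no clusters at all)."""


class GenerationError(CFUError):
    """Synthetic plate generation could not satisfy the requested layout."""
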