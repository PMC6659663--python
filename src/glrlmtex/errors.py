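"""Typed exceptions raised by the GLRLM pipeline.

All inherit from :class:`GLRLMError` so callers (notably the CLI) can
catch one base class and translate it into a nonzero exit code.
"""


class GLRLMError(Exception):
    """Base class for all errors raised by this package."""


class ShapeError(GLRLMError):
    """Input grid is empty or not rectangular."""


class RangeError(GLRLMError):
    """A pixel intensity lies outside [0, gl_resolution)."""


class GeometryError(GLRLMError):
    """ROI geometry does not fit inside the image."""


class CapacityError(GLRLMError):
    """The 63-bit key bound num_ROI_index_bound * G * roi_length would overflow."""


class ConsistencyError(GLRLMError):
    """An internal engine contract was violated (indicates a bug)."""


class DivisionDomainError(GLRLMError):
    """An inverse-square gray-level weight met level 0 (intensity 0 with offset 0)."""


class CompletenessError(GLRLMError):
    """A feature table does not cover every ROI position of the requested map."""
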