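"""Exception hierarchy for the markalign package."""


class MarkAlignError(Exception):
    """Base class for all markalign errors."""


class DimensionError(MarkAlignError):
    """Image/kernel dimensions are incompatible with the requested operation."""


class ParameterError(MarkAlignError):
    """A parameter violates its contract (e.g. even kernel size, radius < 2)."""


class DetectionFailureError(MarkAlignError):
    """Fewer than three credible circle peaks were found in a match map."""


class RoleAssignmentError(MarkAlignError):
    """Triad role assignment is degenerate (collinear or ambiguous points)."""


class RenderSpecError(MarkAlignError):
    """A synthetic render spec is invalid (e.g. mark outside the frame)."""


class DegenerateTraceError(MarkAlignError):
    """An intensity trace has no usable plateau difference to normalize by."""


class ConfigError(MarkAlignError):
    """Invalid or unknown configuration keys/values."""
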