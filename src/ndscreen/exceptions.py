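"""Exception hierarchy for ndscreen.

All package-specific errors derive from :class:`NdscreenError` so callers can
catch the whole family; the subclasses distinguish malformed files, violated
domain invariants, configuration problems, failed model fits and dead-surface
data-quality conditions.
"""


class NdscreenError(Exception):
    """Base class for all ndscreen errors."""


class FormatError(NdscreenError):
    """A file could not be parsed (missing column, bad number, bad layout)."""


class ValidationError(NdscreenError):
    """Parsed data violate a domain invariant (duplicate cycle, bad marker order)."""


class AlignmentError(NdscreenError):
    """Two sensorgrams cannot be aligned (non-overlapping time spans)."""


class ConfigError(NdscreenError):
    """A configuration key is unknown, missing or has an invalid value."""


class FitError(NdscreenError):
    """A least-squares fit failed (rank deficiency, non-convergence, degenerate data)."""


class DataQualityError(NdscreenError):
    """The data are unusable for the requested step (e.g. dead control surface)."""
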