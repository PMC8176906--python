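"""Exception hierarchy for the lcvmap pipeline.

Every stage raises a subclass of :class:`LcvmapError` so the CLI can turn
any failure into a one-line diagnostic with the stage name attached.
"""


class LcvmapError(Exception):
    """Base class for all lcvmap errors."""


class ParameterError(LcvmapError, ValueError):
    """An invalid parameter value (negative size, even window, ...)."""


class InputError(LcvmapError, ValueError):
    """Invalid or inconsistent input data (shape mismatch, degenerate grid)."""


class AlignmentError(InputError):
    """Two grids do not share footprint, cell size or georeferencing."""


class FormatError(LcvmapError, ValueError):
    """A file does not carry the metadata the format requires."""


class LegendError(LcvmapError, ValueError):
    """A categorical grid value has no entry in its legend."""


class ConfigurationError(LcvmapError, ValueError):
    """A configuration table is missing a required key."""


class GenerationError(LcvmapError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class DegenerateRangeError(LcvmapError, ValueError):
    """A min-max rescale was asked of a constant matrix."""


class EmptyInputError(InputError):
    """An operation received an all-nodata or empty grid."""
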