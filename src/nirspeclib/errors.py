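"""Exception hierarchy.

Every failure mode the public API promises is a distinct subclass of
:class:`NIRSpecLibError`, so callers can catch the whole family or a
specific contract violation.
"""


class NIRSpecLibError(Exception):
    """Base class for all package errors."""


class FormatError(NIRSpecLibError):
    """A file could not be parsed (missing column, malformed block)."""


class ValidationError(NIRSpecLibError):
    """An input violates a structural precondition (grid, lengths, metadata)."""


class RangeError(NIRSpecLibError):
    """A requested grid or interval extends beyond the available span."""


class RegionError(NIRSpecLibError):
    """A wavenumber region selects no grid points."""


class DegenerateInputError(NIRSpecLibError):
    """An input has zero variance where variance is required."""


class EmptySelectionError(NIRSpecLibError):
    """A selection or filter matched no entries."""


class CoverageError(NIRSpecLibError):
    """The library cannot cover the target r_T range on at least one side."""


class SizeError(NIRSpecLibError):
    """Too few samples for the requested operation."""


class RankError(NIRSpecLibError):
    """Requested number of latent variables / components is infeasible."""


class DataError(NIRSpecLibError):
    """Required reference assay values are absent."""


class ConfigurationError(NIRSpecLibError):
    """An invalid configuration combination."""
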