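"""Exception hierarchy for the crosspet pipeline.

All pipeline errors derive from :class:`CrosspetError` so callers can catch
one base class; subclasses distinguish bad user input from degenerate data.
"""


class CrosspetError(Exception):
    """Base class for all crosspet errors."""


class InvalidMetadataError(CrosspetError, ValueError):
    """Acquisition metadata violates its invariants (weight, dose, half-life)."""


class ChronologyError(CrosspetError, ValueError):
    """Scan time precedes injection time."""


class ResolutionError(CrosspetError, ValueError):
    """Resampling would leave fewer than two voxels along some axis."""


class NoLesionError(CrosspetError, ValueError):
    """Segmentation found no positive uptake to seed from."""


class MaskConflictError(CrosspetError, ValueError):
    """Tumor and normal-tissue masks overlap or are otherwise inconsistent."""


class ParameterError(CrosspetError, ValueError):
    """A configuration parameter is out of its valid range."""


class DegenerateDataError(CrosspetError, ValueError):
    """The data are too degenerate for the requested statistic (e.g. constant x)."""


class SpecError(CrosspetError, ValueError):
    """A synthetic-data specification is infeasible (lesion outside grid, bad r2)."""
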