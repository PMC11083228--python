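"""Exception hierarchy for the ultradce pipeline.

Stage-level failures are fatal (missing files, wrong dimensionality);
voxel- and ROI-level failures are fail-soft and surface as validity
masks or dropped summaries instead of exceptions.
"""


class UltraDceError(Exception):
    """Base class for all pipeline errors."""


class DimensionError(UltraDceError):
    """Input volume does not have the expected dimensionality."""


class ConfigurationError(UltraDceError):
    """Required configuration (e.g. frame timing) is missing or invalid."""


class GridMismatchError(UltraDceError):
    """Two volumes that must share a spatial grid do not."""


class EmptyRoiError(UltraDceError):
    """A region of interest contains no voxels."""


class DetectionError(UltraDceError):
    """Bolus arrival could not be detected (e.g. flat curve)."""


class WindowError(UltraDceError):
    """An analysis window is empty or ill-posed (e.g. arrival too early)."""


class DomainError(UltraDceError):
    """Parameter values outside the mathematical domain of an operation."""


class FitError(UltraDceError):
    """A curve fit cannot be attempted (e.g. too few weighted frames)."""


class InsufficientDataError(UltraDceError):
    """A statistical analysis lacks the groups or observations it needs."""


class AccountingError(UltraDceError):
    """Cohort exclusion counts are inconsistent."""
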