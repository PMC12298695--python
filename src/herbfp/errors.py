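"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`HerbfpError`
so callers can catch one type at a pipeline boundary.
"""


class HerbfpError(Exception):
    """Base class for all errors raised by herbfp."""


class ConfigurationError(HerbfpError):
    """Invalid generator or pipeline configuration (non-positive rates, bad ranges...)."""


class FormatError(HerbfpError):
    """Malformed fingerprint or manifest file; message names the offending row."""


class GridError(HerbfpError):
    """Time grids are incompatible (mismatched, non-overlapping, or not covering)."""


class RegionError(HerbfpError):
    """Fingerprint-region selection is empty or ill-ordered."""


class ParameterError(HerbfpError):
    """Operation parameters violate their preconditions."""


class DegenerateRowError(HerbfpError):
    """A row-wise transform hit a zero-variance row; message names the sample."""


class StratificationError(HerbfpError):
    """A cross-validation fold's training part lost one of the classes."""


class DimensionError(HerbfpError):
    """Feature dimensions of data and model disagree."""


class TrainingError(HerbfpError):
    """Model training is impossible on the given data (e.g. a single class)."""


class ComparabilityError(HerbfpError):
    """Evaluation reports built on different splits cannot be tabulated together."""
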