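"""Exception hierarchy for the myofuse pipelines.

Every error raised by the package derives from :class:`MyofuseError`, so
callers (and the CLI) can catch pipeline failures without masking genuine
programming errors.
"""


class MyofuseError(Exception):
    """Base class for all myofuse errors."""


class FormatError(MyofuseError):
    """Input file is not a readable image of a supported format."""


class CalibrationError(MyofuseError):
    """Pixel size in µm is missing or unusable (never silently defaulted)."""


class ConfigurationError(MyofuseError):
    """Channel-order mapping or run configuration is inconsistent."""


class GeometryError(MyofuseError):
    """Array dimensions of images/masks/label maps do not match."""


class ParameterError(MyofuseError):
    """A pipeline parameter is out of its documented range."""


class DegenerateImageError(MyofuseError):
    """Image histogram has fewer than two distinct levels; no threshold exists."""


class LabelMapError(MyofuseError):
    """Label map violates the consecutive-1..n labelling contract."""


class NoSingletonsError(MyofuseError):
    """No singleton nuclei available: the modal area (clump divisor) is undefined."""


class FeasibilityError(MyofuseError):
    """Synthetic scene cannot be placed within the requested geometry."""


class RequiredInputError(MyofuseError):
    """A mandatory user input (e.g. the manual small-cell nuclei count) is missing."""


class InconsistencyError(MyofuseError):
    """Counts violate the fusion-index preconditions (outside + small > total)."""


class UndefinedIndexError(MyofuseError):
    """Fusion index is undefined because the total nuclei count is zero."""


class StatisticError(MyofuseError):
    """Correlation statistic is undefined (n < 3 or zero variance)."""
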