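"""Exception hierarchy shared across the package."""


class WoodchangeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(WoodchangeError, ValueError):
    """An input, parameter, or config file value is invalid."""


class GridMismatchError(WoodchangeError, ValueError):
    """Two layers that must share a grid do not."""


class NotSupportedError(WoodchangeError, NotImplementedError):
    """The operation requires capabilities deliberately out of scope
    (e.g. reprojection between coordinate reference systems)."""


class PlacementError(WoodchangeError, RuntimeError):
    """Spatially constrained sampling could not place the requested points."""


class UndefinedResultError(WoodchangeError, ValueError):
    """A statistic is undefined for the given inputs (e.g. zero variance)."""
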