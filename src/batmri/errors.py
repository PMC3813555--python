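"""Exception hierarchy for batmri.

Errors are grouped so callers (and the CLI) can distinguish configuration
mistakes from data problems from numerical degeneracies.
"""


class BatmriError(Exception):
    """Base class for all batmri errors."""


class ConfigError(BatmriError):
    """Invalid configuration or specification parameters."""


class UnrepresentableDistributionError(ConfigError):
    """Requested moments cannot be represented by the skew-normal family."""


class GeometryError(ConfigError):
    """Depot geometry is invalid (overlap, outside grid, negative size)."""


class CongruenceError(BatmriError):
    """Two grids that must share shape/spacing do not."""


class SeedPlacementError(BatmriError):
    """A segmentation seed lies outside the eligible set (or a depot)."""


class ProtocolError(ConfigError):
    """Segmentation protocol violated (seed counts, radii, iteration range)."""


class EmptyRoiError(BatmriError):
    """A region mask is empty where statistics were requested."""


class LayoutError(BatmriError):
    """Rater table is not a complete two-way subject x rater layout."""


class InsufficientDataError(BatmriError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(BatmriError):
    """Zero-variance or constant data where a ratio/correlation is undefined."""
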