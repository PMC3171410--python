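"""Typed errors raised by gazeframe.

Every invalid input either parses cleanly or raises one of these; no
partially constructed datasets or maps escape a constructor.
"""


class GazeframeError(Exception):
    """Base class for all gazeframe errors."""


class FormatError(GazeframeError):
    """A file does not conform to the expected tabular/matrix format."""


class GeometryError(GazeframeError):
    """Shapes, scales or display geometry are inconsistent."""


class EmptyDatasetError(GazeframeError):
    """An operation that needs at least one fixation received none."""


class ConfigError(GazeframeError):
    """An unknown strategy/method name or an invalid configuration value."""


class DegenerateCoverageError(GazeframeError):
    """Chao-Shen coverage is zero (every observation is a singleton).

    The coverage-adjusted estimator is undefined in this regime; collect
    more samples or use a coarser binning.
    """
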