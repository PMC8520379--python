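"""Exception hierarchy shared by all endostitch modules."""


class EndostitchError(Exception):
    """Base class for all errors raised by this package."""


class InputFormatError(EndostitchError):
    """An input image or file has an unsupported layout or dtype."""


class ParameterError(EndostitchError, ValueError):
    """A numeric argument is outside its valid range."""


class ConfigurationError(EndostitchError):
    """A configuration value is inconsistent with the data it is applied to."""


class DataValidationError(EndostitchError):
    """A bundled or user-supplied data table violates its invariants."""


class EstimationError(EndostitchError):
    """Geometric model estimation failed (too few or degenerate matches)."""


class DivergentModelError(EndostitchError):
    """An estimated transform maps a frame to an implausibly large canvas."""


class FixtureSpecError(EndostitchError):
    """A synthetic-fixture specification cannot produce a valid image pair."""
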