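"""Exception hierarchy shared across the package."""


class FootstrikeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FootstrikeError):
    """Invalid configuration value (unknown class label, bad threshold, ...)."""


class InputError(FootstrikeError):
    """Malformed or insufficient input data."""


class FormatError(InputError):
    """A file on disk violates the expected column/value contract."""


class NoStanceError(FootstrikeError):
    """Loading-rate thresholds were never crossed: no stance phase found."""


class DegenerateStanceError(FootstrikeError):
    """A stance window from which no meaningful features can be computed."""


class NotFittedError(FootstrikeError):
    """A model was asked to predict before being fitted."""
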