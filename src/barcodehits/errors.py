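"""Exception hierarchy shared across the pipeline."""


class BarcodeHitsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BarcodeHitsError, ValueError):
    """A caller violated an operation precondition (bad rank name, empty label...)."""


class ParseError(BarcodeHitsError, ValueError):
    """A data file could not be parsed; the message names the offending line."""


class ConfigError(BarcodeHitsError, ValueError):
    """A dialect/run configuration references things that do not exist or is inconsistent."""


class DataError(BarcodeHitsError, RuntimeError):
    """Inputs parsed fine but are unusable for the requested computation."""
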