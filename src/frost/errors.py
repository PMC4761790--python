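"""Exception hierarchy shared by all pipeline stages."""


class FrostError(Exception):
    """Base class for all errors raised by this package."""


class InputError(FrostError):
    """Malformed or contract-violating input data."""


class EstimationError(FrostError):
    """An estimator could not produce a valid result (e.g. invalid bracket)."""
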