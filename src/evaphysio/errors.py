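"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A scenario or analysis configuration is invalid (bad task code, empty schedule, ...)."""


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect (missing column, bad header)."""


class DataError(ValueError):
    """File parsed but violates a data invariant (non-monotone time, overlapping intervals)."""
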