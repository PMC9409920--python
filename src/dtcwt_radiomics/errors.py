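"""Exception hierarchy shared across the pipeline stages."""


class InputError(ValueError):
    """Malformed or inconsistent input (shape mismatch, non-finite values, ...)."""


class ShapeMismatchError(InputError):
    """Two grids that must share a shape do not."""


class EmptyROIError(ValueError):
    """An operation that needs in-mask pixels received an empty mask."""


class ConfigurationError(ValueError):
    """A configuration object violates its invariants."""


class DegenerateDataError(ValueError):
    """Data degenerate for the requested statistic (e.g. zero pooled variance)."""
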