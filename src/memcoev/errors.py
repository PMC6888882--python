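"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """An input violates a documented precondition."""


class ConfigurationError(ValueError):
    """A simulation configuration is unusable (e.g. dt so large that p_i > 1)."""


class FitFailureError(RuntimeError):
    """A fit could not be performed (degenerate data or exhausted budget)."""


class UndefinedResultError(ValueError):
    """The requested statistic is undefined on this input (e.g. 0/0)."""
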