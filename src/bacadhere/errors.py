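"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A physical parameter violates its validity domain (e.g. E* <= 0)."""


class CalibrationError(RuntimeError):
    """The sampler calibration system has no solution with sigma > 0."""


class UnbalancedDesignError(ValueError):
    """The factorial layout is unbalanced; the ANOVA here is balanced-only."""
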