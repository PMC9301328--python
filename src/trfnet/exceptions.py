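"""Package-specific exception types."""


class FitError(RuntimeError):
    """A model fit failed numerically (e.g. rank-deficient covariance)."""


class DegenerateVarianceError(ValueError):
    """A statistic is undefined because the within-pair variance is zero."""
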