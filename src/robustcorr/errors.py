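"""Exception types shared across the package."""


class InsufficientDataError(ValueError):
    """Raised when a sample is too small for the requested estimator."""


class DegenerateDataError(ValueError):
    """Raised when an estimate is undefined for the given data.

    Typical causes: a robust scale of zero (more than half the values
    tied), all residuals identically zero, or a constant variable.
    Raising instead of returning NaN keeps non-finite values out of
    downstream distance and p-value matrices.
    """
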