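"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent or out of range."""


class IdentifiabilityError(ValueError):
    """A requested model cannot identify its target coefficient.

    Raised e.g. when the instrument is collinear with per-hospital indicator
    dummies (the instrument is constant within hospital by construction) or
    when a degenerate design removes the coefficient of interest.
    """


class DegenerateInputError(ValueError):
    """Input data is structurally degenerate (empty hospital, constant outcome...)."""
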