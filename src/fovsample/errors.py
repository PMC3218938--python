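"""Exception hierarchy shared across the package."""


class FovSampleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FovSampleError):
    """A user-supplied configuration value is unusable (missing column, bad flag)."""


class ValidationError(FovSampleError):
    """Input data violates a structural invariant."""


class FittingError(FovSampleError):
    """A model fit failed or did not converge; carries optimizer diagnostics."""


class UnsupportedStructureError(FovSampleError):
    """The input lacks the structure an operation requires (e.g. no ROI labels)."""
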