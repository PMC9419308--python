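"""Exception types shared across the pipeline."""


class DietnetError(Exception):
    """Base class for all package errors."""


class ValidationError(DietnetError):
    """Input table or configuration violates a schema invariant."""


class NotPositiveDefiniteError(DietnetError):
    """A requested or estimated precision matrix is not positive definite."""


class ConvergenceError(DietnetError):
    """An iterative solver failed to reach its tolerance."""
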