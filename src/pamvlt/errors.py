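"""Exception and warning types shared across the package."""


class PamVltError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PamVltError):
    """Invalid survey or zone configuration (bin widths, bounds, ...)."""


class InputError(PamVltError):
    """Invalid user-supplied data (empty click list, negative distance, ...)."""


class SchemaError(PamVltError):
    """A table file does not match the documented CSV schema."""


class ValidationError(PamVltError):
    """A table parses but violates an integrity constraint."""


class EstimationError(PamVltError):
    """A fit cannot be computed (no detections, unidentifiable g(0), ...)."""


class InvalidStateError(PamVltError):
    """A latent-state vector violates the no-re-entry constraint."""


class ConvergenceWarning(UserWarning):
    """An MCMC fit shows R-hat at or above the 1.1 threshold."""


class EstimationWarning(UserWarning):
    """A fit produced draws that required flagging or dropping."""
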