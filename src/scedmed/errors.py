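"""Exception hierarchy. Every error carries a short machine-readable ``code``."""


class SCEDError(Exception):
    """Base class for all scedmed errors."""

    code = "sced_error"

    def __init__(self, message: str, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class ConfigurationError(SCEDError):
    """User-supplied configuration is invalid (bad column map, bad mode, ...)."""

    code = "configuration"


class ValidationError(SCEDError):
    """Input data violates a structural invariant (time order, phase blocks, bounds)."""

    code = "validation"


class InfeasibleError(SCEDError):
    """Data are structurally valid but too sparse/degenerate for the requested analysis."""

    code = "infeasible"
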