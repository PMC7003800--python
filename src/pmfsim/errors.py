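"""Exception hierarchy for pmfsim."""


class PmfsimError(Exception):
    """Base class for all pmfsim errors."""


class InvalidParameterError(PmfsimError, ValueError):
    """A parameter violates its documented domain."""


class ConfigError(PmfsimError, ValueError):
    """A configuration document is malformed or contains unknown keys.

    ``key_path`` locates the offending entry (dotted path into the document).
    """

    def __init__(self, message: str, key_path: str | None = None):
        self.key_path = key_path
        if key_path:
            message = f"{message} (at '{key_path}')"
        super().__init__(message)


class EquilibrationError(PmfsimError, RuntimeError):
    """Dark equilibration failed to reach a fixed point.

    Carries the per-component derivative residuals for inspection.
    """

    def __init__(self, message: str, residuals: dict | None = None):
        self.residuals = residuals or {}
        if self.residuals:
            worst = max(self.residuals, key=lambda k: abs(self.residuals[k]))
            message = f"{message}; worst residual {worst}={self.residuals[worst]:.3e}"
        super().__init__(message)


class IntegrationError(PmfsimError, RuntimeError):
    """ODE integration failed or produced an invalid state.

    ``last_time``/``last_state`` hold the last accepted point, ``term`` the
    offending flux or state component when known.
    """

    def __init__(self, message: str, last_time: float | None = None,
                 last_state=None, term: str | None = None):
        self.last_time = last_time
        self.last_state = last_state
        self.term = term
        if term:
            message = f"{message} (term: {term})"
        if last_time is not None:
            message = f"{message} [last good t={last_time:.6g} s]"
        super().__init__(message)
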