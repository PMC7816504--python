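"""Exception types shared across the solver stack."""


class SeepFSIError(RuntimeError):
    """Base class for solver failures."""


class ConvergenceError(SeepFSIError):
    """Inner pressure-velocity iterations failed to reach the residual tolerance.

    Carries the residual history of the failing step so the caller can
    inspect how the iteration stalled.
    """

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class DivergenceError(SeepFSIError):
    """The solution left its physical bounds (NaN fields, wall displacement
    beyond half the radius, ...) — the usual signature of a blown-up coupling."""


class CouplingDivergenceError(DivergenceError):
    """FSI sub-iterations exhausted without interface convergence."""

    def __init__(self, message, residual_trace=None):
        super().__init__(message)
        self.residual_trace = list(residual_trace or [])
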