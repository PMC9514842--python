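"""Exception hierarchy for mixedsyn."""


class MixedSynError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(MixedSynError):
    """Non-positive diameter or otherwise impossible soma geometry."""


class IntegrationError(MixedSynError):
    """The integrator produced a non-finite state; reports the step size used."""

    def __init__(self, message: str, dt: float | None = None):
        super().__init__(message)
        self.dt = dt


class ProtocolViolationError(MixedSynError):
    """A virtual experiment violated its contract (e.g. wrong spike count)."""


class InsufficientDataError(MixedSynError):
    """Fewer sweeps/samples than the analysis procedure requires."""


class FitFailureError(MixedSynError):
    """Nonlinear fit failed to converge; carries diagnostics."""


class CannotIsolateError(MixedSynError):
    """Chemical-component isolation is undefined without failure sweeps."""


class WindowTruncationError(MixedSynError):
    """A decay never reached the required fraction of peak within the record."""
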