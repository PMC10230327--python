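"""Exception hierarchy for the clearwing package."""


class ClearwingError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ClearwingError, ValueError):
    """An input violates a documented precondition or invariant."""


class SimulationError(ClearwingError, RuntimeError):
    """An electromagnetic simulation failed (Courant violation, unconverged run)."""


class NoContactError(ClearwingError, ValueError):
    """The fitted droplet circle does not intersect the baseline."""


class FitError(ClearwingError, RuntimeError):
    """A least-squares fit is degenerate (e.g. collinear contour points)."""
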