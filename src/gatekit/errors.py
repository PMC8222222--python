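"""Exception hierarchy shared across gatekit modules."""


class GatekitError(Exception):
    """Base class for all gatekit-specific errors."""


class FormatError(GatekitError, ValueError):
    """A bundle or table on disk is missing fields or carries ill-typed values."""


class ShapeError(GatekitError, ValueError):
    """Array dimensions are inconsistent (ragged sweeps, mismatched axes)."""


class ArgumentError(GatekitError, ValueError):
    """An argument violates a documented precondition."""


class FitError(GatekitError, RuntimeError):
    """A least-squares fit failed to converge from every start."""


class EstimationError(GatekitError, RuntimeError):
    """A quantity cannot be estimated from the data (e.g. no zero crossing)."""
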