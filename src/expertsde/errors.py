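"""Exception hierarchy shared by all modules."""


class ExpertSDEError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ExpertSDEError, ValueError):
    """A numeric parameter violates an operation's preconditions."""


class NoStationaryDistributionError(ExpertSDEError, ValueError):
    """Raised when stationary moments are requested for a non-mean-reverting
    process (state gain >= 0): the process has no stationary distribution."""


class StructuralError(ExpertSDEError, ValueError):
    """A game tree violates a structural invariant.

    Carries the offending node id in ``node_id`` when one can be named.
    """

    def __init__(self, message: str, node_id: str | None = None):
        super().__init__(message if node_id is None else f"{message} (node {node_id!r})")
        self.node_id = node_id


class ConvergenceError(ExpertSDEError, RuntimeError):
    """Fixed-point iteration failed to reach tolerance.

    ``residual`` holds the last max-norm probability change observed.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual
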