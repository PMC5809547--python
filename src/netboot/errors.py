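"""Exception types shared across the package."""


class NetbootError(Exception):
    """Base class for netboot errors."""


class DegenerateVariableError(NetbootError, ValueError):
    """A variable carries no information (constant, or a single category)."""


class ConvergenceError(NetbootError, RuntimeError):
    """An iterative estimator failed to converge."""


class NotRepresentableError(NetbootError, ValueError):
    """A partial-correlation network has no Gaussian representation
    (its implied precision matrix is not positive definite)."""
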