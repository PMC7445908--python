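"""Exception hierarchy shared across the package.

Each error class carries the process exit code used by the command-line
interface, so shell pipelines can distinguish bad input (2) from a
non-identifiable design (3) and a fit that failed to converge (4).
"""


class APCError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(APCError):
    """Malformed or inconsistent input data or configuration."""

    exit_code = 2


class IdentificationError(APCError):
    """The design matrix null space does not have dimension one."""

    exit_code = 3

    def __init__(self, message: str, null_dim: int | None = None):
        super().__init__(message)
        self.null_dim = null_dim


class ConvergenceError(APCError):
    """Iteratively reweighted least squares did not converge.

    ``deviance_trace`` holds the deviance after each iteration, which is
    usually enough to diagnose oscillation versus divergence.
    """

    exit_code = 4

    def __init__(self, message: str, deviance_trace=None):
        super().__init__(message)
        self.deviance_trace = list(deviance_trace) if deviance_trace is not None else []
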