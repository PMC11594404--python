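"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes so that batch pipelines can
distinguish malformed inputs from numerical breakdowns and from cluster
counts the data cannot support.
"""


class GemLRError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GemLRError):
    """Input does not match the declared shape, names, or value domain."""

    exit_code = 2


class NumericalError(GemLRError):
    """A computation lost all numerical mass (underflow, singularity)."""

    exit_code = 3


class InfeasibleClusterError(GemLRError):
    """The requested number of clusters leaves a component empty.

    Parameters
    ----------
    requested : int
        The cluster count that failed.
    max_feasible : int or None
        Largest cluster count found to fit without an empty component,
        when the caller asked for that diagnostic.
    """

    exit_code = 4

    def __init__(self, requested: int, max_feasible: int | None = None,
                 message: str | None = None):
        self.requested = requested
        self.max_feasible = max_feasible
        if message is None:
            message = f"empty cluster encountered while fitting C={requested}"
            if max_feasible is not None:
                message += f"; largest feasible cluster count is {max_feasible}"
        super().__init__(message)
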