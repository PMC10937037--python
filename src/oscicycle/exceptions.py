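"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`ArgumentError` -> 2, :class:`NumericalError` -> 3.
"""


class OscicycleError(Exception):
    """Base class for all package errors."""


class ArgumentError(OscicycleError, ValueError):
    """Invalid argument, configuration or file content."""


class SizeError(ArgumentError):
    """Problem size exceeds a combinatorial-explosion guard."""


class StructureError(ArgumentError):
    """Graph structure violates a precondition (e.g. a cycle where a DAG is required)."""


class NumericalError(OscicycleError, RuntimeError):
    """Numerical failure during integration or linear algebra."""


class IntegrationError(NumericalError):
    """NaN/overflow during time integration; carries the offending time index."""

    def __init__(self, message: str, time_index: int | None = None):
        super().__init__(message)
        self.time_index = time_index
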