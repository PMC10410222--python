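"""Exception types shared across the package.

Analytic functions raise typed errors instead of returning NaN so that
root solvers and the CLI can react to invalid geometry cleanly.
"""


class SheetVoidError(Exception):
    """Base class for all package errors."""


class DomainError(SheetVoidError, ValueError):
    """An input lies outside the mathematical domain of a relation."""


class GeometryError(SheetVoidError, ValueError):
    """A parameter combination does not describe a physical cell geometry."""


class NoVoidSolutionError(GeometryError):
    """The requested porosity leaves no room for voids (negative void volume).

    Carries the offending value (e.g. the negative Omega) in ``value``.
    """

    def __init__(self, message: str, value: float | None = None):
        super().__init__(message)
        self.value = value


class ConfigError(SheetVoidError, ValueError):
    """A run configuration is malformed or internally inconsistent."""


class ContainmentError(SheetVoidError, RuntimeError):
    """Molecules left the simulation ensemble before the run finished."""

    def __init__(self, message: str, first_escape_time: float | None = None,
                 left_count: int = 0):
        super().__init__(message)
        self.first_escape_time = first_escape_time
        self.left_count = left_count


class NotConvergedError(SheetVoidError, RuntimeError):
    """A time course never reached a steady-state plateau."""


class TortuosityUnreachableError(SheetVoidError, ValueError):
    """The fitted tortuosity curve never attains the requested target."""
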