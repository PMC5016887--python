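"""Exception hierarchy shared across the package."""


class CimdsError(Exception):
    """Base class for all package-specific errors."""


class EdgeListParseError(CimdsError):
    """An edge-list line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class EmptyNetworkError(CimdsError):
    """An operation that requires a non-empty network received an empty one."""


class UnknownNodeError(CimdsError):
    """A referenced node is not a member of the network."""


class UnknownTissueError(CimdsError):
    """A referenced tissue is absent from the expression calls."""


class ConfigurationError(CimdsError):
    """Invalid or incomplete run configuration (e.g. a missing expression threshold)."""


class SolverError(CimdsError):
    """The integer-programming backend failed to prove optimality."""


class SizeCapError(CimdsError):
    """The exhaustive enumeration oracle was asked for a graph above its node cap."""


class ConsistencyError(CimdsError):
    """Cross-structure inconsistency, e.g. an MDS member outside its tissue network."""
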