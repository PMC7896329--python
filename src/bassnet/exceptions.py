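"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain."""


class EdgeListParseError(ValueError):
    """An edge-list line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, line: str, reason: str = "expected at least two tokens"):
        self.line_number = line_number
        self.line = line
        super().__init__(f"line {line_number}: {reason}: {line!r}")


class DegenerateCentralityError(ValueError):
    """All betweenness scores are equal; no meaningful 'most central' node exists."""


class InfeasibilityError(RuntimeError):
    """The requested diffusion outcome has probability zero (e.g. beta-only
    spread on a disconnected graph can never reach every node)."""


class NoLD50InRangeError(RuntimeError):
    """Even the maximum dose of 1.0 saturates the network in fewer than half
    of trials, so no LD50 exists in (0, 1]."""


class GraphTooLargeError(ValueError):
    """The exact Markov-chain oracle refuses graphs above its enumeration guard."""


class InvalidTransitionError(ValueError):
    """A Markov transition was requested that would un-adopt a node."""
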