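"""Exception hierarchy for network validation and wave construction."""


class QlbnError(Exception):
    """Base class for all errors raised by this package."""


class NetworkValidationError(QlbnError):
    """A network specification violates a structural invariant."""


class CyclicGraphError(NetworkValidationError):
    """The directed graph induced by the conditional tables has a cycle."""


class MissingTableError(NetworkValidationError):
    """A declared variable has no conditional probability table."""


class DuplicateTableError(NetworkValidationError):
    """More than one conditional probability table refers to the same child."""


class RowSumError(NetworkValidationError):
    """A conditional distribution row does not sum to one."""


class InvalidProbabilityError(QlbnError):
    """A probability value lies outside [0, 1]."""


class UnsupportedQueryError(QlbnError):
    """The query variable is not binary; only two-outcome queries are supported."""


class ImpossibleEvidenceError(QlbnError):
    """The observed evidence has probability zero under the network."""


class MismatchedWaveError(QlbnError):
    """Two waves that must share the same configuration count do not."""


class InfeasiblePhaseError(QlbnError):
    """No counterpart phase balances the requested phase (arccos argument outside [-1, 1])."""


class PrincipleDispatchError(QlbnError):
    """The entropy/mirror principle was invoked on intervals that do not satisfy its precondition."""
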