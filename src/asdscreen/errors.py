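"""Exception hierarchy.

Errors are split along the lines a caller can act on: bad numeric input
(:class:`DomainError`), a missing table entry (:class:`UnknownGroupError`),
ill-formed configuration or records (:class:`ValidationError`,
:class:`ConfigurationError`), and measurements that fall outside what the
classification scheme can interpret (:class:`AnomalousObservationError`).
"""


class AsdscreenError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AsdscreenError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class UnknownGroupError(AsdscreenError, KeyError):
    """A structural group label is absent from the contribution table."""

    def __init__(self, label: str, method: str):
        self.label = label
        self.method = method
        super().__init__(f"group {label!r} not present in the {method} table")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class UnsupportedMethodError(AsdscreenError, ValueError):
    """An operation requires a different group-contribution method."""


class ConfigurationError(AsdscreenError, ValueError):
    """Inconsistent configuration (mixed methods, unknown mode, bad paths)."""


class ValidationError(AsdscreenError, ValueError):
    """A record or table violates a structural invariant."""


class AnomalousObservationError(AsdscreenError, ValueError):
    """An observation cannot be assigned any miscibility class.

    Raised e.g. for a single glass transition far below both pure-component
    values, where plasticization by residual solvent is the likely cause and
    silently labelling the sample would hide a real problem.
    """


class DegenerateMatrixError(AsdscreenError, ValueError):
    """A feature matrix has too few informative columns to decompose."""
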