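"""Exception hierarchy shared across the package."""


class SolvoptimError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SolvoptimError, ValueError):
    """An argument violates a documented precondition."""


class MissingFeatureError(SolvoptimError, KeyError):
    """A requested feature cannot be resolved for a solvent."""

    def __init__(self, solvent_id: str, feature: str):
        self.solvent_id = solvent_id
        self.feature = feature
        super().__init__(f"feature {feature!r} unresolvable for solvent {solvent_id!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class NumericalConditioningError(SolvoptimError, RuntimeError):
    """A linear-algebra step failed even after jitter escalation."""


class UnsupportedConfigError(SolvoptimError, ValueError):
    """The requested operation is not supported under the current configuration."""


class UndefinedQuantityError(SolvoptimError, ValueError):
    """A statistic is undefined for the given data (e.g. zero-variance targets)."""


class ExhaustedLibraryError(SolvoptimError, RuntimeError):
    """No untested candidates remain to suggest."""


class DegenerateLabelsError(SolvoptimError, ValueError):
    """Classification requested on single-class data."""


class SchemaError(SolvoptimError, ValueError):
    """An input file does not conform to the documented schema."""


class OracleInterruption(SolvoptimError, RuntimeError):
    """An oracle call failed mid-loop; carries the checkpointed state."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state
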