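"""Exception hierarchy shared across the toolkit."""


class TrialSqlError(Exception):
    """Base class for all toolkit errors."""


class UnknownDomainError(TrialSqlError):
    """A domain_id has no rule in the CDM registry."""


class UnknownConceptError(TrialSqlError):
    """A concept_id is not present in the inventory."""


class FormatError(TrialSqlError):
    """A delimited vocabulary file is missing a required column."""


class IntegrityError(TrialSqlError):
    """A vocabulary file violates a uniqueness or referential constraint."""


class InputError(TrialSqlError):
    """An operation received an out-of-contract input value."""


class SqlParseError(TrialSqlError):
    """SQL text failed the structural parse check."""


class BuildError(TrialSqlError):
    """A criterion query could not be rendered."""


class AssemblyError(TrialSqlError):
    """A cohort query could not be assembled (e.g. zero inclusions)."""


class SchemaValidationError(TrialSqlError):
    """A backend output failed validation against the expected record schema."""


class ScriptedMissError(TrialSqlError):
    """The mock backend has no scripted response for the given input."""


class FeasibilityError(TrialSqlError):
    """A requested synthetic target is not achievable for the given sizes."""

    def __init__(self, message: str, nearest: float | None = None):
        super().__init__(message)
        self.nearest = nearest


class InjectionError(TrialSqlError):
    """Error injection could not honour the requested profile."""


class DegenerateInputError(TrialSqlError):
    """A statistic is undefined for the given table (e.g. zero discordants)."""
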