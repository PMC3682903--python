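"""Exception hierarchy for the phenovalid pipeline.

Every failure mode the pipeline distinguishes maps to one class here; the
CLI translates them to exit codes (config/usage -> 1, data integrity -> 2,
marginal inconsistency -> 3).
"""


class PhenovalidError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhenovalidError):
    """Invalid or infeasible configuration."""


class SchemaError(PhenovalidError):
    """Input file does not conform to the documented schema."""


class IntegrityError(PhenovalidError):
    """Referential or uniqueness violation in input data."""


class DomainError(PhenovalidError):
    """Operation called outside its mathematical domain (e.g. empty cohort)."""


class InconsistencyError(PhenovalidError):
    """Marginal counts admit no non-negative joint distribution."""

    def __init__(self, message: str, pattern=None, class_label: str | None = None):
        super().__init__(message)
        self.pattern = pattern
        self.class_label = class_label
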