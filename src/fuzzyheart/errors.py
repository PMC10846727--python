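"""Exception hierarchy for the fuzzy expert system."""


class FuzzyHeartError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FuzzyHeartError):
    """A variable or rule configuration is malformed or inconsistent."""


class DomainError(FuzzyHeartError, ValueError):
    """A crisp value lies outside a variable's universe of discourse."""


class RecordValidationError(DomainError):
    """One or more fields of a patient record are out of range.

    Aggregates every offending field so the caller sees the full list
    at once rather than one failure per attempt.
    """

    def __init__(self, problems: dict[str, str]):
        self.problems = dict(problems)
        lines = "; ".join(f"{k}: {v}" for k, v in self.problems.items())
        super().__init__(f"invalid patient record ({lines})")


class RuleParseError(FuzzyHeartError, ValueError):
    """An IF-THEN rule sentence could not be parsed."""


class IntegrityError(FuzzyHeartError):
    """A rule store violates structural constraints (e.g. duplicate antecedents)."""


class EngineError(FuzzyHeartError):
    """Inference failed, e.g. an antecedent combination missing from a partial rule base."""


class DefuzzificationError(FuzzyHeartError):
    """Defuzzification is undefined for the given activation (no fired rule, zero area)."""
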