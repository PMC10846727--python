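"""End-to-end diagnosis facade tying the pipeline stages together."""

from __future__ import annotations

from dataclasses import dataclass, field

from .defuzz import DiagnosisResult, defuzz_combined
from .engine import fire
from .rules import RuleBase, generate_rule_base
from .variables import PatientRecord, VariableModel, load_variables


@dataclass
class DiagnosisSystem:
    """The full expert system: variable model + rule base + inference.

    With no arguments, loads the shipped heart-disease model and
    generates the complete 4320-rule knowledge base.
    """

    model: VariableModel = field(default_factory=load_variables)
    rulebase: RuleBase | None = None

    def __post_init__(self) -> None:
        if self.rulebase is None:
            self.rulebase = generate_rule_base(self.model)

    def diagnose(self, record: PatientRecord) -> DiagnosisResult:
        """Fuzzify → fire rules (MIN/MAX) → clip → defuzzify → classify."""
        fz = self.model.fuzzify_record(record)
        act = fire(self.rulebase, fz)
        return defuzz_combined(act, self.model.output)

    def diagnose_values(self, chest_pain: float, hba1c: float, hdl: float,
                        ldl: float, heart_rate: float, age: float,
                        blood_pressure: float) -> DiagnosisResult:
        return self.diagnose(PatientRecord(
            chest_pain=chest_pain, hba1c=hba1c, hdl=hdl, ldl=ldl,
            heart_rate=heart_rate, age=age, blood_pressure=blood_pressure,
        ))
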