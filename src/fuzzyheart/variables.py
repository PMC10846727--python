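"""Linguistic variables, patient records, and fuzzification.

The shipped model has seven input variables — chest-pain type (crisp
codes 1/3/5/7), HbA1c (%), HDL and LDL cholesterol (mg/dL), heart rate
(bpm), age (years), systolic blood pressure (mmHg) — and one output
variable, a 0–10 heart-disease risk score partitioned into Healthy /
LowRisk / MediumRisk / HighRisk.  Terms of every variable are ordered
by increasing risk contribution (for the protective HDL that means
Healthy before Low).

Variable definitions live in a human-editable YAML file; the default
model ships with the package and is validated through a pydantic
schema on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigurationError, DomainError, RecordValidationError
from .membership import DEGREE_EPS, MembershipFunction

#: Canonical input variable order used everywhere (antecedent tuples,
#: CSV columns, CLI flags).
INPUT_ORDER = (
    "chest_pain",
    "hba1c",
    "hdl",
    "ldl",
    "heart_rate",
    "age",
    "blood_pressure",
)

OUTPUT_NAME = "result"


@dataclass(frozen=True)
class LinguisticVariable:
    """A named attribute whose values are described by fuzzy sets."""

    name: str
    display_name: str
    units: str
    universe: tuple[float, float]
    terms: tuple[MembershipFunction, ...]
    role: Literal["input", "output"] = "input"
    #: Ordinal risk score per term (same order as ``terms``), used by
    #: the rule generator; non-decreasing in term order.
    risk_scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ConfigurationError(f"{self.name}: empty universe [{lo}, {hi}]")
        names = [t.term for t in self.terms]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"{self.name}: duplicate term names {names}")
        for t in self.terms:
            s_lo, s_hi = t.support(self.universe)
            if s_lo < lo - 1e-9 or s_hi > hi + 1e-9:
                raise ConfigurationError(
                    f"{self.name}.{t.term}: support [{s_lo}, {s_hi}] "
                    f"outside universe [{lo}, {hi}]"
                )
        if self.risk_scores and len(self.risk_scores) != len(self.terms):
            raise ConfigurationError(
                f"{self.name}: {len(self.risk_scores)} risk scores for "
                f"{len(self.terms)} terms"
            )

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(t.term for t in self.terms)

    def term(self, name: str) -> MembershipFunction:
        for t in self.terms:
            if t.term == name:
                return t
        raise ConfigurationError(
            f"variable {self.name!r} has no term {name!r}; terms are {self.term_names}"
        )

    def check_in_range(self, x: float) -> None:
        lo, hi = self.universe
        if not (isinstance(x, (int, float)) and math.isfinite(x)) or not lo <= x <= hi:
            raise DomainError(
                f"{self.name}={x!r} outside valid range [{lo}, {hi}] {self.units}"
            )

    def membership(self, term: str, x: float) -> float:
        """Degree of ``x`` in ``term``; exact at breakpoints, linear between."""
        mf = self.term(term)
        self.check_in_range(x)
        return mf.degree(x)

    def fuzzify(self, x: float) -> dict[str, float]:
        """All nonzero term degrees at ``x`` (zero-degree terms omitted)."""
        self.check_in_range(x)
        out = {}
        for t in self.terms:
            d = t.degree(x)
            if d >= DEGREE_EPS:
                out[t.term] = d
        return out


@dataclass(frozen=True)
class PatientRecord:
    """Crisp values of the seven input attributes for one patient."""

    chest_pain: float
    hba1c: float
    hdl: float
    ldl: float
    heart_rate: float
    age: float
    blood_pressure: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INPUT_ORDER}


@dataclass(frozen=True)
class FuzzifiedRecord:
    """Per-variable map term → degree for one patient, plus the crisp values."""

    degrees: dict[str, dict[str, float]]
    crisp: PatientRecord

    def degree(self, variable: str, term: str) -> float:
        return self.degrees.get(variable, {}).get(term, 0.0)


@dataclass(frozen=True)
class VariableModel:
    """The complete set of linguistic variables (seven inputs + one output)."""

    inputs: dict[str, LinguisticVariable]
    output: LinguisticVariable

    def __post_init__(self) -> None:
        missing = [n for n in INPUT_ORDER if n not in self.inputs]
        if missing:
            raise ConfigurationError(f"model missing input variables: {missing}")

    def __iter__(self) -> Iterator[LinguisticVariable]:
        return iter(self.inputs.values())

    def input(self, name: str) -> LinguisticVariable:
        try:
            return self.inputs[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown input variable {name!r}; inputs are {list(self.inputs)}"
            ) from None

    def fuzzify_record(self, record: PatientRecord) -> FuzzifiedRecord:
        """Fuzzify all seven inputs, validating every field first.

        Out-of-range fields are collected into a single aggregated
        error naming each offending field and its valid range, so a
        form or CSV row can be fixed in one pass.
        """
        problems: dict[str, str] = {}
        for name in INPUT_ORDER:
            var = self.inputs[name]
            try:
                var.check_in_range(getattr(record, name))
            except DomainError as e:
                problems[name] = str(e)
        if problems:
            raise RecordValidationError(problems)
        degrees = {
            name: self.inputs[name].fuzzify(getattr(record, name))
            for name in INPUT_ORDER
        }
        return FuzzifiedRecord(degrees=degrees, crisp=record)


# ---------------------------------------------------------------------------
# serialization


class _TermSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    term: str
    shape: str
    vertices: list[tuple[float, float]]
    right_closed: bool = False


class _VariableSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    display_name: str
    units: str
    universe: tuple[float, float]
    role: Literal["input", "output"] = "input"
    terms: list[_TermSchema]
    risk_scores: list[float] = []


class _ModelSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variables: dict[str, _VariableSchema]


def _build_variable(name: str, schema: _VariableSchema) -> LinguisticVariable:
    terms = tuple(
        MembershipFunction(
            term=t.term,
            shape=t.shape,
            vertices=tuple((float(x), float(d)) for x, d in t.vertices),
            right_closed=t.right_closed,
        )
        for t in schema.terms
    )
    return LinguisticVariable(
        name=name,
        display_name=schema.display_name,
        units=schema.units,
        universe=(float(schema.universe[0]), float(schema.universe[1])),
        terms=terms,
        role=schema.role,
        risk_scores=tuple(float(s) for s in schema.risk_scores),
    )


def load_variables(path: str | Path | None = None) -> VariableModel:
    """Load a variable model from YAML (the shipped default if no path).

    Raises :class:`ConfigurationError` with the offending location on
    schema violations (e.g. a degree outside [0, 1]).
    """
    if path is None:
        text = resources.files("fuzzyheart.data").joinpath("heart_model.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
        schema = _ModelSchema.model_validate(raw)
    except (yaml.YAMLError, ValidationError) as e:
        raise ConfigurationError(f"invalid variable config: {e}") from e

    inputs: dict[str, LinguisticVariable] = {}
    output: LinguisticVariable | None = None
    for name, var_schema in schema.variables.items():
        var = _build_variable(name, var_schema)
        if var.role == "output":
            if output is not None:
                raise ConfigurationError("more than one output variable in config")
            output = var
        else:
            inputs[name] = var
    if output is None:
        raise ConfigurationError("config defines no output variable")
    return VariableModel(inputs=inputs, output=output)


def save_variables(model: VariableModel, path: str | Path) -> None:
    """Write a variable model back to YAML (inverse of :func:`load_variables`)."""
    doc: dict = {"variables": {}}
    for var in list(model.inputs.values()) + [model.output]:
        entry: dict = {
            "display_name": var.display_name,
            "units": var.units,
            "universe": [float(var.universe[0]), float(var.universe[1])],
            "role": var.role,
            "terms": [
                {
                    "term": t.term,
                    "shape": t.shape,
                    "vertices": [[float(x), float(d)] for x, d in t.vertices],
                    **({"right_closed": True} if t.right_closed else {}),
                }
                for t in var.terms
            ],
        }
        if var.risk_scores:
            entry["risk_scores"] = [float(s) for s in var.risk_scores]
        doc["variables"][var.name] = entry
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)
    )
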