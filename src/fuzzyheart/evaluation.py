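"""Batch diagnosis, classification accuracy, and synthetic fixtures.

The accuracy of the system over a labeled set of records is the
fraction of records whose predicted class equals the given label,
reported as a percentage (correct / total * 100).  Records with
out-of-range fields are rejected — counted and reported separately,
never clamped — mirroring the input validation of the interactive
path.

The fixture generator produces labeled patient records entirely in
memory so the whole test suite runs without any external dataset:
uniform random records and universe-corner records are labeled by
running the shipped pipeline itself (self-labeled), while
class-archetype records are built from the peaks of a curated rule's
antecedent terms and labeled with that rule's class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FuzzyHeartError, RecordValidationError
from .rules import OUTPUT_CLASSES
from .variables import INPUT_ORDER, PatientRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledRecord:
    record: PatientRecord
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in OUTPUT_CLASSES:
            raise ValueError(
                f"label {self.label!r} not one of {OUTPUT_CLASSES}"
            )


@dataclass(frozen=True)
class AccuracyReport:
    n_total: int
    n_correct: int
    accuracy_pct: float
    confusion: pd.DataFrame
    n_rejected: int = 0

    def __str__(self) -> str:
        return (f"accuracy {self.accuracy_pct:.2f}% "
                f"({self.n_correct}/{self.n_total} correct, "
                f"{self.n_rejected} rejected)")


def classification_accuracy(n_correct: int, n_total: int) -> float:
    """Correct / total * 100, in percent."""
    if n_total < 1:
        raise ValueError("need at least one record")
    return n_correct / n_total * 100.0


def evaluate(records: list[LabeledRecord], system) -> AccuracyReport:
    """Diagnose every labeled record and tabulate accuracy.

    ``system`` is anything with a ``diagnose(PatientRecord) ->
    DiagnosisResult`` method.  Out-of-range records are excluded from
    the totals and logged.
    """
    confusion = pd.DataFrame(
        0, index=list(OUTPUT_CLASSES), columns=list(OUTPUT_CLASSES), dtype=int
    )
    n_rejected = 0
    for i, lr in enumerate(records):
        if lr.label is None:
            raise ValueError(f"record {i} has no label")
        try:
            result = system.diagnose(lr.record)
        except RecordValidationError as e:
            n_rejected += 1
            logger.warning("record %d rejected: %s", i, e)
            continue
        confusion.loc[lr.label, result.label] += 1
    n_total = int(confusion.to_numpy().sum())
    if n_total == 0:
        raise ValueError("no valid records to evaluate")
    n_correct = int(np.trace(confusion.to_numpy()))
    return AccuracyReport(
        n_total=n_total,
        n_correct=n_correct,
        accuracy_pct=classification_accuracy(n_correct, n_total),
        confusion=confusion,
        n_rejected=n_rejected,
    )


# ---------------------------------------------------------------------------
# fixture generation

#: Archetype antecedents, one curated rule per output class.  Records
#: are built from each term's peak value, so the archetype rule fires
#: with strength 1 and the pipeline agrees with the archetype label.
_ARCHETYPES: dict[str, dict[str, str]] = {
    "Healthy": {
        "chest_pain": "NoPain", "hba1c": "VeryHealthy", "hdl": "Healthy",
        "ldl": "Healthy", "heart_rate": "VeryHealthy", "age": "Young",
        "blood_pressure": "Normal",
    },
    "LowRisk": {
        "chest_pain": "NonAnginal", "hba1c": "Healthy", "hdl": "Healthy",
        "ldl": "High", "heart_rate": "Healthy", "age": "Mid",
        "blood_pressure": "Normal",
    },
    "MediumRisk": {
        "chest_pain": "Atypical", "hba1c": "High", "hdl": "Low",
        "ldl": "VeryHigh", "heart_rate": "VeryHealthy", "age": "Mid",
        "blood_pressure": "Normal",
    },
    "HighRisk": {
        "chest_pain": "Atypical", "hba1c": "High", "hdl": "Low",
        "ldl": "VeryHigh", "heart_rate": "VeryHealthy", "age": "Mid",
        "blood_pressure": "High",
    },
}

#: Crisp chest-pain codes (No Pain / Non Anginal / Atypical / Typical).
CHEST_PAIN_CODES = (1.0, 3.0, 5.0, 7.0)

FIXTURE_MODES = ("random-uniform", "grid-corners", "class-archetypes")


def generate_fixtures(n: int, seed: int, mode: str = "random-uniform",
                      system=None, archetype: str | None = None) -> list[LabeledRecord]:
    """Generate ``n`` labeled in-range patient records.

    ``system`` (a :class:`~fuzzyheart.system.DiagnosisSystem`) labels
    random and grid records by running the pipeline; archetype records
    carry their archetype class and need no system.  Same seed, same
    records, bit for bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in FIXTURE_MODES:
        raise ValueError(f"mode must be one of {FIXTURE_MODES}")

    if mode == "class-archetypes":
        return _archetype_records(n, system, archetype)

    if system is None:
        from .system import DiagnosisSystem
        system = DiagnosisSystem()
    model = system.model

    records: list[PatientRecord] = []
    if mode == "random-uniform":
        rng = np.random.default_rng(seed)
        for _ in range(n):
            values = {}
            for name in INPUT_ORDER:
                if name == "chest_pain":
                    values[name] = float(rng.choice(CHEST_PAIN_CODES))
                else:
                    lo, hi = model.input(name).universe
                    values[name] = float(rng.uniform(lo, hi))
            records.append(PatientRecord(**values))
    else:  # grid-corners: cycle the 2^7 universe-corner combinations
        corners = [model.input(name).universe for name in INPUT_ORDER]
        for i in range(n):
            bits = [(i >> b) & 1 for b in range(len(INPUT_ORDER))]
            values = {
                name: float(corners[j][bits[j]])
                for j, name in enumerate(INPUT_ORDER)
            }
            records.append(PatientRecord(**values))

    return [
        LabeledRecord(record=r, label=system.diagnose(r).label) for r in records
    ]


def _archetype_records(n: int, system, archetype: str | None) -> list[LabeledRecord]:
    if archetype is not None and archetype not in _ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; one of {list(_ARCHETYPES)}")
    if system is None:
        from .system import DiagnosisSystem
        system = DiagnosisSystem()
    model = system.model
    classes = [archetype] if archetype else list(_ARCHETYPES)
    out: list[LabeledRecord] = []
    for i in range(n):
        cls = classes[i % len(classes)]
        values = {
            name: model.input(name).term(term).peak(model.input(name).universe)
            for name, term in _ARCHETYPES[cls].items()
        }
        out.append(LabeledRecord(record=PatientRecord(**values), label=cls))
    return out


# ---------------------------------------------------------------------------
# CSV I/O  (columns: chest_pain,hba1c,hdl,ldl,heart_rate,age,blood_pressure[,label])


def write_labeled_csv(records: list[LabeledRecord], path: str | Path) -> None:
    rows = []
    for lr in records:
        row = lr.record.as_dict()
        if lr.label is not None:
            row["label"] = lr.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labeled_csv(path: str | Path) -> list[LabeledRecord]:
    """Read patient records (optionally labeled) from CSV.

    Unknown columns are accepted with a warning; a non-numeric value in
    a numeric column raises with its row number (1-based, excluding
    the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in INPUT_ORDER if c not in df.columns]
    if missing:
        raise FuzzyHeartError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in (*INPUT_ORDER, "label")]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)

    records: list[LabeledRecord] = []
    for i, row in df.iterrows():
        values = {}
        for name in INPUT_ORDER:
            try:
                values[name] = float(row[name])
            except (TypeError, ValueError):
                raise FuzzyHeartError(
                    f"{path}: row {i + 1}: column {name!r} has "
                    f"non-numeric value {row[name]!r}"
                ) from None
        label = None
        if "label" in df.columns and pd.notna(row["label"]):
            label = str(row["label"])
        records.append(LabeledRecord(record=PatientRecord(**values), label=label))
    return records
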