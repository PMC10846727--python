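"""Mamdani inference: rule firing by MIN aggregation and output clipping.

A rule's firing strength is the minimum of its seven antecedent
membership degrees (the AND connective).  Rules sharing a consequent
combine by maximum, and each fired consequent triangle is clipped at
its strength (Mamdani implication).  Firing walks only the Cartesian
product of the record's *active* terms — at most 2 per variable, so at
most 2^7 index lookups — rather than scanning all 4320 rules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import DefuzzificationError, EngineError
from .membership import DEGREE_EPS, Polyline, clip_polyline
from .rules import Rule, RuleBase
from .variables import INPUT_ORDER, FuzzifiedRecord, LinguisticVariable


@dataclass(frozen=True)
class ActivationSet:
    """Firing strengths per output term, with the full fired-rule trace."""

    strengths: dict[str, float]
    trace: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(not (0.0 < s <= 1.0) for s in self.strengths.values()):
            raise ValueError(f"strengths must lie in (0, 1]: {self.strengths}")


def rule_strength(rule: Rule, fz: FuzzifiedRecord) -> float:
    """MIN over the rule's seven antecedent degrees (absent term → 0)."""
    return min(fz.degree(var, term) for var, term in rule.antecedent.items())


def fire(rb: RuleBase, fz: FuzzifiedRecord) -> ActivationSet:
    """Fire all applicable rules against a fuzzified record.

    Only antecedent combinations built from the record's active terms
    are looked up.  With a complete rule base every combination is
    present; a missing one (partial base) raises :class:`EngineError`
    naming the tuple.
    """
    active = [tuple(fz.degrees[var].items()) for var in INPUT_ORDER]
    strengths: dict[str, float] = {}
    trace: list[tuple[int, float]] = []
    for combo in itertools.product(*active):
        key = tuple(term for term, _ in combo)
        strength = min(deg for _, deg in combo)
        if strength < DEGREE_EPS:
            continue
        rule = rb.get(key)
        if rule is None:
            raise EngineError(f"no rule for active antecedent {key}")
        trace.append((rule.id, strength))
        prev = strengths.get(rule.consequent, 0.0)
        strengths[rule.consequent] = max(prev, strength)
    return ActivationSet(strengths=strengths, trace=tuple(trace))


def fire_brute_force(rb: RuleBase, fz: FuzzifiedRecord) -> ActivationSet:
    """Reference implementation scanning every rule; used for cross-checks."""
    strengths: dict[str, float] = {}
    trace: list[tuple[int, float]] = []
    for rule in rb.rules:
        s = rule_strength(rule, fz)
        if s < DEGREE_EPS:
            continue
        trace.append((rule.id, s))
        strengths[rule.consequent] = max(strengths.get(rule.consequent, 0.0), s)
    return ActivationSet(strengths=strengths, trace=tuple(trace))


def clip_outputs(act: ActivationSet,
                 output: LinguisticVariable) -> dict[str, Polyline]:
    """Clip each fired consequent's membership curve at its firing strength.

    Returns one exact polyline per fired term (kept separate so the
    area defuzzifier can weight each consequent set individually); the
    pointwise-MAX aggregate is available via :func:`aggregate_envelope`.
    """
    if not act.strengths:
        raise DefuzzificationError("no rule fired; nothing to defuzzify")
    return {
        term: clip_polyline(output.term(term).polyline(output.universe), s)
        for term, s in act.strengths.items()
    }


def aggregate_envelope(clipped: dict[str, Polyline], x):
    """Pointwise maximum of the clipped consequent curves at ``x``."""
    import numpy as np

    from .membership import eval_polyline

    vals = [np.asarray(eval_polyline(pts, x)) for pts in clipped.values()]
    return np.maximum.reduce(vals)
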