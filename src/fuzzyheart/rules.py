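"""The IF-THEN knowledge base: rule DSL, generation, and flat-file store.

A rule is a conjunction of exactly one linguistic term per input
variable ("Chest Pain is Atypical AND HbA1c is High AND ...") with one
output-class consequent.  The complete knowledge base covers every
antecedent combination — 4 x 3 x 2 x 5 x 3 x 4 x 3 = 4320 rules — and
is indexed by antecedent tuple for O(1) retrieval during inference.

Because only a handful of rules are published as expert knowledge, the
remaining consequents are filled in by a deterministic weighted
ordinal risk score: each term carries an ordinal score in risk order,
each variable a weight (by default proportional to the magnitude of
its term-midpoint correlation with the output classes), and the
normalized 0-10 sum is thresholded into the four classes.  The curated
expert rules are applied on top as hard overrides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError, IntegrityError, RuleParseError
from .variables import INPUT_ORDER, VariableModel

OUTPUT_CLASSES = ("Healthy", "LowRisk", "MediumRisk", "HighRisk")

#: Normalized-score cut points between the four classes; a score on a
#: threshold goes to the riskier class (conservative clinical default).
DEFAULT_THRESHOLDS = (2.5, 5.0, 7.5)


@dataclass(frozen=True)
class Rule:
    """One IF-THEN rule: a full antecedent over the 7 inputs and a consequent."""

    id: int
    antecedent: dict[str, str]
    consequent: str
    provenance: str = "generated"

    def __post_init__(self) -> None:
        missing = [v for v in INPUT_ORDER if v not in self.antecedent]
        extra = [v for v in self.antecedent if v not in INPUT_ORDER]
        if missing or extra:
            raise ConfigurationError(
                f"rule {self.id}: antecedent must cover exactly the 7 inputs "
                f"(missing {missing}, unknown {extra})"
            )
        if self.consequent not in OUTPUT_CLASSES:
            raise ConfigurationError(
                f"rule {self.id}: unknown consequent {self.consequent!r}"
            )

    @property
    def antecedent_tuple(self) -> tuple[str, ...]:
        """Antecedent terms in canonical input-variable order."""
        return tuple(self.antecedent[v] for v in INPUT_ORDER)


@dataclass
class RuleBase:
    """An indexed collection of rules, at most one per antecedent tuple."""

    rules: list[Rule] = field(default_factory=list)
    index: dict[tuple[str, ...], Rule] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index:
            for r in self.rules:
                self._index(r)

    def _index(self, rule: Rule) -> None:
        key = rule.antecedent_tuple
        if key in self.index:
            raise IntegrityError(
                f"duplicate antecedent {key}: rules {self.index[key].id} and {rule.id}"
            )
        self.index[key] = rule

    def add(self, rule: Rule) -> None:
        self._index(rule)
        self.rules.append(rule)

    def get(self, antecedent: tuple[str, ...]) -> Rule | None:
        return self.index.get(antecedent)

    def __len__(self) -> int:
        return len(self.rules)


# ---------------------------------------------------------------------------
# rule-text DSL

# variable-name aliases, normalized (lowercase, alphanumeric only)
_VARIABLE_ALIASES = {
    "chestpain": "chest_pain",
    "hba1c": "hba1c",
    "haemoglobina1c": "hba1c",
    "hemoglobina1c": "hba1c",
    "hdl": "hdl",
    "ldl": "ldl",
    "heartrate": "heart_rate",
    "age": "age",
    "bloodpressure": "blood_pressure",
    "bp": "blood_pressure",
    "status": "__consequent__",
    "result": "__consequent__",
}

# per-variable term synonyms seen in published rule text, normalized
_TERM_SYNONYMS = {
    "ldl": {"xhigh": "ExtraHigh", "extrahigh": "ExtraHigh"},
    "age": {"middle": "Mid"},
    "hba1c": {"normal": "Healthy"},
    "heart_rate": {"normal": "Healthy"},
    "__consequent__": {"norisk": "Healthy"},
}


def _norm(token: str) -> str:
    return re.sub(r"[^a-z0-9]", "", token.lower())


def _canonical_term(variable: str, raw: str, model: VariableModel) -> str:
    key = _norm(raw)
    key = _TERM_SYNONYMS.get(variable, {}).get(key, key)
    names = (
        OUTPUT_CLASSES if variable == "__consequent__" else model.input(variable).term_names
    )
    for name in names:
        if _norm(name) == _norm(key) or name == key:
            return name
    raise RuleParseError(
        f"unknown term {raw!r} for variable {variable!r}; expected one of {names}"
    )


def parse_rule_text(text: str, model: VariableModel, rule_id: int = 0,
                    provenance: str = "curated") -> Rule:
    """Parse an IF-THEN sentence into a canonical :class:`Rule`.

    Accepts both the "Var is Term AND ..." dialect and the
    "Var: Term; ..." dialect, in any clause order.  Term synonyms are
    normalized (``XHigh`` → ``ExtraHigh``, ``Middle`` → ``Mid``,
    ``Normal`` HbA1c/heart rate → ``Healthy``).
    """
    m = re.search(r"\bif\b(.*?)\bthen\b(.*)$", text, re.IGNORECASE | re.DOTALL)
    if m is None:
        # headless dialect: "If (...) Status is <Class>"
        m = re.search(r"\bif\b\s*(\(.*\))\s*((?:status|result)\b.*)$",
                      text, re.IGNORECASE | re.DOTALL)
    if m is None:
        raise RuleParseError(f"cannot find IF/THEN structure in: {text!r}")
    if_part, then_part = m.group(1), m.group(2)
    if_part = if_part.strip().strip("()")

    clauses = [c for c in re.split(r"\bAND\b|;", if_part, flags=re.IGNORECASE) if c.strip()]
    antecedent: dict[str, str] = {}
    for pos, clause in enumerate(clauses, start=1):
        cm = re.match(r"\s*([A-Za-z0-9 ]+?)\s*(?:\bis\b|:)\s*(.+?)\s*$",
                      clause, re.IGNORECASE)
        if not cm:
            raise RuleParseError(f"clause {pos}: cannot parse {clause.strip()!r}")
        var_key = _VARIABLE_ALIASES.get(_norm(cm.group(1)))
        if var_key is None or var_key == "__consequent__":
            raise RuleParseError(
                f"clause {pos}: unknown input variable {cm.group(1).strip()!r}"
            )
        if var_key in antecedent:
            raise RuleParseError(f"clause {pos}: duplicate variable {var_key!r}")
        antecedent[var_key] = _canonical_term(var_key, cm.group(2), model)

    missing = [v for v in INPUT_ORDER if v not in antecedent]
    if missing:
        raise RuleParseError(f"antecedent missing variables: {missing}")

    tm = re.search(r"(?:\bstatus\b|\bresult\b)\s*(?:\bis\b|:)\s*([A-Za-z ]+?)\s*$",
                   then_part, re.IGNORECASE)
    if not tm:
        raise RuleParseError(f"cannot parse consequent from: {then_part.strip()!r}")
    consequent = _canonical_term("__consequent__", tm.group(1), model)
    return Rule(id=rule_id, antecedent=antecedent, consequent=consequent,
                provenance=provenance)


# ---------------------------------------------------------------------------
# infix -> postfix (shunting-yard) for boolean rule expressions

_PRECEDENCE = {"AND": 2, "OR": 1}


def infix_to_postfix(expr: str | list[str]) -> list[str]:
    """Convert a boolean AND/OR expression with parentheses to postfix.

    Operands are any non-operator tokens; AND binds tighter than OR and
    both are left-associative.
    """
    if isinstance(expr, str):
        tokens = re.findall(r"\(|\)|[^\s()]+", expr)
    else:
        tokens = list(expr)
    out: list[str] = []
    stack: list[str] = []
    for tok in tokens:
        up = tok.upper()
        if up in _PRECEDENCE:
            while stack and stack[-1] in _PRECEDENCE and \
                    _PRECEDENCE[stack[-1]] >= _PRECEDENCE[up]:
                out.append(stack.pop())
            stack.append(up)
        elif tok == "(":
            stack.append(tok)
        elif tok == ")":
            while stack and stack[-1] != "(":
                out.append(stack.pop())
            if not stack:
                raise RuleParseError(f"unbalanced parentheses in {expr!r}")
            stack.pop()
        else:
            out.append(tok)
    while stack:
        op = stack.pop()
        if op == "(":
            raise RuleParseError(f"unbalanced parentheses in {expr!r}")
        out.append(op)
    return out


def eval_postfix(postfix: list[str], values: dict[str, float]) -> float:
    """Evaluate a postfix boolean/fuzzy expression (AND=min, OR=max)."""
    stack: list[float] = []
    for tok in postfix:
        if tok == "AND":
            b, a = stack.pop(), stack.pop()
            stack.append(min(a, b))
        elif tok == "OR":
            b, a = stack.pop(), stack.pop()
            stack.append(max(a, b))
        else:
            stack.append(values[tok])
    if len(stack) != 1:
        raise RuleParseError(f"malformed postfix expression {postfix!r}")
    return stack[0]


# ---------------------------------------------------------------------------
# curated expert rules (published sample rules + the worked diagnostic case)

CURATED_RULE_TEXTS = [
    "If (Chest Pain is Non Anginal AND LDL is High AND HDL is Healthy AND HbA1c is Healthy"
    " AND Heart Rate is Healthy AND Blood Pressure is Normal AND Age is Mid)"
    " Then Status is Low Risk",
    "If (Chest Pain is Atypical AND LDL is XHigh AND HbA1c is Healthy AND HDL is Low"
    " AND Heart Rate is Very Healthy AND Blood Pressure is Normal AND Age is Mid)"
    " Then Status is Low Risk",
    "If (Chest Pain is Typical AND HbA1c is Healthy AND LDL is XHigh AND HDL is Low"
    " AND Heart Rate is Very Healthy AND Blood Pressure is High AND Age is Mid)"
    " Then Status is Medium Risk",
    "If (Chest Pain is Atypical AND HbA1c is Very Healthy AND LDL is Very Healthy AND HDL is Low"
    " AND Heart Rate is Very Healthy AND Blood Pressure is High AND Age is Mid)"
    " Then Status is Medium Risk",
    "If (Chest Pain is Non Anginal AND HbA1c is High AND LDL is XHigh AND HDL is Low"
    " AND Heart Rate is Healthy AND Blood Pressure is High AND Age is Mid)"
    " Then Status is High Risk",
    "If (HDL is Low AND Chest Pain is Typical AND HbA1c is Healthy AND LDL is XHigh"
    " AND Blood Pressure is High AND Heart Rate is Healthy AND Age is Mid)"
    " Then Status is High Risk",
    "If (LDL is Healthy AND HbA1c is Very Healthy AND Chest Pain is No Pain AND HDL is Healthy"
    " AND Blood Pressure is Normal AND Heart Rate is Very Healthy AND Age is Young)"
    " Then Status is Healthy",
    # the two rules that fire on the worked diagnostic case
    "If (Chest Pain is Atypical AND HbA1c is High AND HDL is Low AND LDL is Very High"
    " AND Heart Rate is Very Healthy AND Age is Mid AND Blood Pressure is Normal)"
    " Then Status is Medium Risk",
    "If (Chest Pain is Atypical AND HbA1c is High AND HDL is Low AND LDL is Very High"
    " AND Heart Rate is Very Healthy AND Age is Mid AND Blood Pressure is High)"
    " Then Status is High Risk",
]


def curated_rules(model: VariableModel) -> list[Rule]:
    """The nine published expert rules, parsed from their original sentences."""
    return [
        parse_rule_text(text, model, rule_id=-(i + 1), provenance="curated")
        for i, text in enumerate(CURATED_RULE_TEXTS)
    ]


# ---------------------------------------------------------------------------
# generation

@dataclass(frozen=True)
class RiskWeights:
    """Per-variable weights and class thresholds for the score generator.

    Term risk scores live on the variables themselves
    (``LinguisticVariable.risk_scores``); this carries the relative
    importance of each variable and the cut points on the normalized
    0-10 score.
    """

    weights: dict[str, float]
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ConfigurationError(f"variable weights must be positive: {self.weights}")
        t = self.thresholds
        if not (t[0] < t[1] < t[2]):
            raise ConfigurationError(f"thresholds must be strictly increasing: {t}")


def default_weights(model: VariableModel) -> RiskWeights:
    """Weights proportional to |Pearson r| of term midpoints vs class midpoints."""
    from .correlation import correlation_report

    report = correlation_report(model)
    return RiskWeights(weights={name: abs(r.r) for name, r in report.items()})


def generate_rule_base(model: VariableModel,
                       weights: RiskWeights | None = None,
                       overrides: list[Rule] | None = None) -> RuleBase:
    """Build the complete knowledge base, one rule per antecedent combination.

    Consequents come from the normalized weighted ordinal risk score
    thresholded into the four classes (ties go to the riskier class);
    rules in ``overrides`` (the curated expert rules by default)
    replace the generated consequent for their antecedent.
    """
    if weights is None:
        weights = default_weights(model)
    if overrides is None:
        overrides = curated_rules(model)

    for name in INPUT_ORDER:
        var = model.input(name)
        if not var.risk_scores:
            raise ConfigurationError(f"variable {name!r} has no risk scores configured")
        if name not in weights.weights:
            raise ConfigurationError(f"no weight configured for variable {name!r}")

    override_map: dict[tuple[str, ...], Rule] = {}
    for r in overrides:
        key = r.antecedent_tuple
        if key in override_map and override_map[key].consequent != r.consequent:
            raise ConfigurationError(
                f"conflicting overrides for antecedent {key}: "
                f"{override_map[key].consequent} vs {r.consequent}"
            )
        override_map[key] = r

    max_sum = sum(
        weights.weights[n] * max(model.input(n).risk_scores) for n in INPUT_ORDER
    )

    rb = RuleBase()
    rule_id = 1
    # odometer over term indices in canonical variable order
    term_lists = [model.input(n).term_names for n in INPUT_ORDER]
    score_lists = [model.input(n).risk_scores for n in INPUT_ORDER]
    idx = [0] * len(INPUT_ORDER)
    while True:
        antecedent = {n: term_lists[i][idx[i]] for i, n in enumerate(INPUT_ORDER)}
        key = tuple(antecedent[n] for n in INPUT_ORDER)
        if key in override_map:
            consequent, provenance = override_map[key].consequent, override_map[key].provenance
        else:
            raw = sum(
                weights.weights[n] * score_lists[i][idx[i]]
                for i, n in enumerate(INPUT_ORDER)
            )
            score = 10.0 * raw / max_sum
            # >= sends a score sitting on a cut point to the riskier class
            cls = sum(score >= t for t in weights.thresholds)
            consequent, provenance = OUTPUT_CLASSES[cls], "generated"
        rb.add(Rule(id=rule_id, antecedent=antecedent, consequent=consequent,
                    provenance=provenance))
        rule_id += 1
        for pos in reversed(range(len(idx))):
            idx[pos] += 1
            if idx[pos] < len(term_lists[pos]):
                break
            idx[pos] = 0
        else:
            break
    return rb


# ---------------------------------------------------------------------------
# flat-file store (TSV: id, 7 antecedent terms in canonical order,
# consequent, provenance)

_HEADER = ["id", *INPUT_ORDER, "consequent", "provenance"]


def save_rules(rb: RuleBase, path: str | Path) -> None:
    lines = ["\t".join(_HEADER)]
    for r in rb.rules:
        lines.append("\t".join([str(r.id), *r.antecedent_tuple, r.consequent, r.provenance]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_rules(path: str | Path) -> RuleBase:
    """Load a rule store; duplicate antecedents raise :class:`IntegrityError`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _HEADER:
        raise IntegrityError(f"{path}: missing or malformed header")
    rb = RuleBase()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_HEADER):
            raise IntegrityError(f"{path}:{lineno}: expected {len(_HEADER)} fields")
        rule = Rule(
            id=int(fields[0]),
            antecedent=dict(zip(INPUT_ORDER, fields[1:8])),
            consequent=fields[8],
            provenance=fields[9],
        )
        rb.add(rule)
    return rb
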