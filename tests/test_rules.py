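"""Rule DSL parsing, postfix conversion, generation, and the flat store."""

import itertools
import time

import pytest

import fuzzyheart as fh
from fuzzyheart.errors import ConfigurationError, IntegrityError, RuleParseError
from fuzzyheart.rules import (CURATED_RULE_TEXTS, OUTPUT_CLASSES, RiskWeights,
                              eval_postfix)
from fuzzyheart.variables import INPUT_ORDER

SAMPLE_RULE = CURATED_RULE_TEXTS[0]


def test_parse_canonicalizes_sample_rule(model):
    rule = fh.parse_rule_text(SAMPLE_RULE, model)
    assert rule.antecedent == {
        "chest_pain": "NonAnginal", "ldl": "High", "hdl": "Healthy",
        "hba1c": "Healthy", "heart_rate": "Healthy",
        "blood_pressure": "Normal", "age": "Mid",
    }
    assert rule.consequent == "LowRisk"


def test_parse_is_clause_order_independent(model):
    scrambled = ("If (Age is Mid AND Blood Pressure is Normal AND HbA1c is Healthy"
                 " AND Heart Rate is Healthy AND HDL is Healthy AND LDL is High"
                 " AND Chest Pain is Non Anginal) Then Status is Low Risk")
    a = fh.parse_rule_text(SAMPLE_RULE, model)
    b = fh.parse_rule_text(scrambled, model)
    assert a.antecedent == b.antecedent and a.consequent == b.consequent


def test_parse_colon_semicolon_dialect_and_synonyms(model):
    text = ("IF (Chest Pain: Non-Anginal; HbA1c: Normal; HDL: Healthy;"
            " LDL: XHigh; Heart Rate: Normal; Age: Middle;"
            " Blood Pressure: Normal) THEN Status is Low Risk")
    rule = fh.parse_rule_text(text, model)
    assert rule.antecedent["hba1c"] == "Healthy"       # Normal -> Healthy
    assert rule.antecedent["ldl"] == "ExtraHigh"       # XHigh -> ExtraHigh
    assert rule.antecedent["age"] == "Mid"             # Middle -> Mid
    assert rule.antecedent["heart_rate"] == "Healthy"


@pytest.mark.parametrize("mutation,match", [
    (lambda t: t.replace(" AND Age is Mid", ""), "missing"),
    (lambda t: t.replace("LDL is High", "LDL is Enormous"), "unknown term"),
    (lambda t: t.replace("HDL is Healthy", "LDL is High"), "duplicate"),
    (lambda t: t.replace("Then Status is Low Risk", ""), "IF/THEN|consequent"),
])
def test_parse_errors(model, mutation, match):
    with pytest.raises(RuleParseError, match=match):
        fh.parse_rule_text(mutation(SAMPLE_RULE), model)


# ---------------------------------------------------------------------------
# infix -> postfix


@pytest.mark.parametrize("expr,expected", [
    ("A AND B AND C", ["A", "B", "AND", "C", "AND"]),
    ("A AND (B OR C)", ["A", "B", "C", "OR", "AND"]),
    ("A OR B AND C", ["A", "B", "C", "AND", "OR"]),
])
def test_infix_to_postfix_examples(expr, expected):
    assert fh.infix_to_postfix(expr) == expected


def test_infix_to_postfix_unbalanced():
    with pytest.raises(RuleParseError):
        fh.infix_to_postfix("A AND (B OR C")
    with pytest.raises(RuleParseError):
        fh.infix_to_postfix("A AND B)")


@pytest.mark.parametrize("expr", [
    "A AND B OR C AND D OR E AND F",
    "(A OR B) AND (C OR (D AND E)) OR F",
    "A AND (B OR (C AND D) OR E) AND F",
    "((A AND B) OR C) AND ((D OR E) AND F)",
])
def test_postfix_matches_truth_table_oracle(expr):
    """Postfix evaluation equals Python's own boolean evaluation of the
    infix expression over all 2^6 truth assignments."""
    py_expr = expr.replace("AND", "and").replace("OR", "or")
    names = ["A", "B", "C", "D", "E", "F"]
    postfix = fh.infix_to_postfix(expr)
    for bits in itertools.product([0, 1], repeat=6):
        env = dict(zip(names, bits))
        expected = eval(py_expr, {}, {k: bool(v) for k, v in env.items()})
        got = eval_postfix(postfix, {k: float(v) for k, v in env.items()})
        assert got == float(expected)


# ---------------------------------------------------------------------------
# generation


def test_generated_base_is_complete(model, rulebase):
    term_lists = [model.input(n).term_names for n in INPUT_ORDER]
    n_combos = 1
    for terms in term_lists:
        n_combos *= len(terms)
    assert len(rulebase) == n_combos == 4320
    for combo in itertools.product(*term_lists):
        assert rulebase.get(combo) is not None


def test_curated_rules_present_with_their_consequents(model, rulebase):
    for rule in fh.curated_rules(model):
        stored = rulebase.get(rule.antecedent_tuple)
        assert stored.consequent == rule.consequent
        assert stored.provenance == "curated"


def test_all_best_terms_maps_to_healthy(rulebase):
    best = ("NoPain", "VeryHealthy", "Healthy", "VeryHealthy", "VeryHealthy",
            "Young", "Normal")
    assert rulebase.get(best).consequent == "Healthy"


def test_all_worst_terms_maps_to_high_risk(rulebase):
    worst = ("Typical", "High", "Low", "ExtraHigh", "High", "VeryOld",
             "VeryHigh")
    assert rulebase.get(worst).consequent == "HighRisk"


def test_generated_consequents_are_risk_monotone(model, rulebase):
    """Swapping any antecedent term for a riskier one never lowers the
    generated consequent class (curated overrides exempt)."""
    rank = {c: i for i, c in enumerate(OUTPUT_CLASSES)}
    term_lists = {n: model.input(n).term_names for n in INPUT_ORDER}
    for rule in rulebase.rules:
        if rule.provenance != "generated":
            continue
        for i, var in enumerate(INPUT_ORDER):
            terms = term_lists[var]
            pos = terms.index(rule.antecedent[var])
            if pos + 1 >= len(terms):
                continue
            riskier = list(rule.antecedent_tuple)
            riskier[i] = terms[pos + 1]
            neighbor = rulebase.get(tuple(riskier))
            if neighbor.provenance != "generated":
                continue
            assert rank[neighbor.consequent] >= rank[rule.consequent]


def test_conflicting_overrides_rejected(model):
    base = fh.curated_rules(model)
    clash = fh.Rule(id=99, antecedent=base[0].antecedent,
                    consequent="HighRisk", provenance="curated")
    with pytest.raises(ConfigurationError, match="conflict"):
        fh.generate_rule_base(model, overrides=base + [clash])


def test_risk_weights_validation():
    with pytest.raises(ConfigurationError):
        RiskWeights(weights={"age": -1.0})
    with pytest.raises(ConfigurationError):
        RiskWeights(weights={"age": 1.0}, thresholds=(5.0, 2.5, 7.5))


# ---------------------------------------------------------------------------
# flat-file store


def test_rule_store_round_trip(model, rulebase, tmp_path):
    path = tmp_path / "rules.tsv"
    fh.save_rules(rulebase, path)
    t0 = time.perf_counter()
    reloaded = fh.load_rules(path)
    elapsed = time.perf_counter() - t0
    assert reloaded.rules == rulebase.rules
    assert set(reloaded.index) == set(rulebase.index)
    assert elapsed < 1.0  # 4320 rules load and re-index quickly


def test_rule_store_duplicate_antecedent(model, tmp_path):
    rule = fh.curated_rules(model)[0]
    rb = fh.RuleBase()
    rb.add(rule)
    path = tmp_path / "rules.tsv"
    fh.save_rules(rb, path)
    line = path.read_text().splitlines()[1]
    dup = line.split("\t")
    dup[0], dup[8] = "2", "HighRisk"
    path.write_text(path.read_text() + "\t".join(dup) + "\n")
    with pytest.raises(IntegrityError, match="duplicate antecedent"):
        fh.load_rules(path)
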