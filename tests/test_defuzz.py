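"""Defuzzifiers: hand-derived values, numeric oracles, and invariants."""

import numpy as np
import pytest

import fuzzyheart as fh
from fuzzyheart.engine import aggregate_envelope, clip_outputs
from fuzzyheart.errors import DefuzzificationError
from fuzzyheart.membership import eval_polyline

# the activation produced by the reference diagnostic case
REF_ACT = {"MediumRisk": 0.7, "HighRisk": 0.3}

# hand integration of the two clipped trapezoids:
#   Medium@0.7: area 0.7*(4+1.2)/2 = 1.82, centroid 6
#   High@0.3:   area 0.3*(4+2.8)/2 = 1.02, centroid 8
#   SA = (6*1.82 + 8*1.02) / 2.84
REF_SA = 19.08 / 2.84

# centroid of the pointwise-MAX union envelope of the same two sets,
# frozen from a 2e6-point numeric oracle (documented alternative
# reading; deliberately NOT what defuzz_sa computes)
REF_UNION_SA = 6.6694


def act(**strengths):
    return fh.ActivationSet(strengths=strengths)


def random_activations(model, n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        terms = rng.choice(model.output.term_names,
                           size=int(rng.integers(1, 5)), replace=False)
        out.append(act(**{t: float(rng.uniform(0.05, 1.0)) for t in terms}))
    return out


@pytest.mark.parametrize("strengths,expected", [
    (REF_ACT, 6.6),                                # (6*.7 + 8*.3) / 1.0
    ({"HighRisk": 1.0}, 8.0),                      # single apex
    ({"MediumRisk": 0.4, "HighRisk": 0.4}, 7.0),   # symmetric strengths
])
def test_wa_examples(model, strengths, expected):
    assert fh.defuzz_wa(act(**strengths), model.output) == pytest.approx(expected)


@pytest.mark.parametrize("strengths,expected", [
    (REF_ACT, REF_SA),
    ({"HighRisk": 1.0}, 8.0),  # centroid of a symmetric triangle
])
def test_sa_examples(model, strengths, expected):
    assert fh.defuzz_sa(act(**strengths), model.output) == pytest.approx(
        expected, abs=1e-12)


def test_sa_union_envelope_variant_differs(model):
    """The centroid of the MAX-union envelope is a different (unused)
    reading of the area method; pin its value to document the gap."""
    clipped = clip_outputs(act(**REF_ACT), model.output)
    x = np.linspace(0, 10, 200_001)
    env = aggregate_envelope(clipped, x)
    union = np.trapezoid(env * x, x) / np.trapezoid(env, x)
    assert union == pytest.approx(REF_UNION_SA, abs=1e-3)
    assert abs(union - fh.defuzz_sa(act(**REF_ACT), model.output)) > 0.04


@pytest.mark.parametrize("strengths,expected", [
    (REF_ACT, 6.0),                                # plateau [5.4, 6.6]
    ({"HighRisk": 1.0}, 8.0),                      # apex
    ({"MediumRisk": 0.5, "HighRisk": 0.5}, 7.0),   # equal plateaus [5,7],[7,9]
    ({"LowRisk": 0.5, "HighRisk": 0.5}, 6.0),      # disjoint equal plateaus
])
def test_mm_examples(model, strengths, expected):
    assert fh.defuzz_mm(act(**strengths), model.output) == pytest.approx(expected)


@pytest.mark.parametrize("strengths,expected", [
    (REF_ACT, (6.6 + REF_SA + 6.0) / 3),
    ({"HighRisk": 1.0}, 8.0),
    ({"Healthy": 1.0}, 2.0),
])
def test_combined_examples(model, strengths, expected):
    res = fh.defuzz_combined(act(**strengths), model.output)
    assert res.crisp == pytest.approx(expected)
    assert res.crisp == pytest.approx((res.wa + res.sa + res.mm) / 3, abs=1e-12)


def test_reference_case_rounds_to_printed_score(model):
    res = fh.defuzz_combined(act(**REF_ACT), model.output)
    assert res.crisp == pytest.approx(6.44, abs=0.01)
    assert res.label == "MediumRisk"


@pytest.mark.parametrize("crisp,expected", [
    (6.44, "MediumRisk"),
    (5.0, "MediumRisk"),   # exact tie resolves to the riskier class
    (3.0, "LowRisk"),
    (7.0, "HighRisk"),     # tie MediumRisk/HighRisk -> riskier
    (0.0, "Healthy"),
    (10.0, "HighRisk"),
])
def test_classify(model, crisp, expected):
    assert fh.classify(crisp, model.output) == expected


def test_empty_activation_rejected(model):
    empty = fh.ActivationSet(strengths={})
    for fn in (fh.defuzz_wa, fh.defuzz_sa, fh.defuzz_mm, fh.defuzz_combined):
        with pytest.raises(DefuzzificationError):
            fn(empty, model.output)


def test_outputs_within_hull_of_active_supports(model):
    for a in random_activations(model, 100, seed=5):
        supports = [model.output.term(t).support(model.output.universe)
                    for t in a.strengths]
        lo = min(s[0] for s in supports)
        hi = max(s[1] for s in supports)
        res = fh.defuzz_combined(a, model.output)
        for value in (res.wa, res.sa, res.mm, res.crisp):
            assert lo - 1e-9 <= value <= hi + 1e-9


def test_shifting_mass_to_riskier_consequent_never_decreases_score(model):
    """Moving firing strength from a lower-risk to a higher-risk
    consequent can only push WA, SA, and the combined score up."""
    rng = np.random.default_rng(9)
    order = model.output.term_names
    for _ in range(100):
        i, j = sorted(rng.choice(len(order), size=2, replace=False))
        s = float(rng.uniform(0.1, 0.9))
        delta = float(rng.uniform(0.01, min(s - 1e-3, 0.5)))
        before = {order[i]: s, order[j]: s}
        after = {order[i]: s - delta, order[j]: s}
        wa0, wa1 = (fh.defuzz_wa(act(**x), model.output) for x in (before, after))
        sa0, sa1 = (fh.defuzz_sa(act(**x), model.output) for x in (before, after))
        assert wa1 >= wa0 - 1e-12
        assert sa1 >= sa0 - 1e-12


def test_sa_matches_numeric_trapezoid_oracle(model):
    """Analytic per-set integration equals a dense numeric trapezoid
    integration of each clipped curve."""
    for a in random_activations(model, 50, seed=13):
        clipped = clip_outputs(a, model.output)
        num_area = num_moment = 0.0
        for pts in clipped.values():
            grid = np.linspace(pts[0][0], pts[-1][0], 100_001)
            y = eval_polyline(pts, grid)
            num_area += np.trapezoid(y, grid)
            num_moment += np.trapezoid(y * grid, grid)
        assert fh.defuzz_sa(a, model.output) == pytest.approx(
            num_moment / num_area, abs=1e-6)


def test_end_to_end_determinism(model, reference_record):
    a = fh.DiagnosisSystem(model=model).diagnose(reference_record)
    b = fh.DiagnosisSystem(model=model).diagnose(reference_record)
    assert (a.wa, a.sa, a.mm, a.crisp, a.label) == \
        (b.wa, b.sa, b.mm, b.crisp, b.label)
    assert a.activation.trace == b.activation.trace
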