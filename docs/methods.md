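# Methods

## Linguistic model

Each of the seven inputs is a linguistic variable over a closed
universe of discourse; values outside the universe are rejected (the
caller is told the valid range), never clamped. Universes and terms:

| variable | universe | terms (risk-increasing order) |
|---|---|---|
| chest_pain | [0, 8] code | NoPain, NonAnginal, Atypical, Typical (crisp) |
| hba1c | [3, 14] % | VeryHealthy, Healthy, High |
| hdl | [10, 80] mg/dL | Healthy, Low |
| ldl | [40, 200] mg/dL | VeryHealthy, Healthy, High, VeryHigh, ExtraHigh |
| heart_rate | [40, 160] bpm | VeryHealthy, Healthy, High |
| age | [20, 120] years | Young, Mid, Old, VeryOld |
| blood_pressure | [80, 240] mmHg | Normal, High, VeryHigh |
| result (output) | [0, 10] score | Healthy, LowRisk, MediumRisk, HighRisk |

All graded memberships are piecewise linear with 0.5-to-20-unit
transition ramps placed so that adjacent terms are exactly
complementary: the terms of every graded variable form a partition of
unity (Σ degrees = 1 at every point, verified to 1e-9 on 10,000-point
grids), and at most two terms are ever active. The boundary terms are
shoulders that saturate at 1 toward one end of the universe.

Chest pain is categorical — a patient has exactly one pain type — so
its four sets are crisp intervals of width 2 centered on the codes 1,
3, 5, 7. The intervals are half-open ([0,2), [2,4), [4,6), [6,8]) so
that every admissible value activates exactly one term. The width-2
choice is a modeling decision; only the four codes themselves are
meaningful inputs, and the interval midpoints coincide with them.

The output classes are symmetric triangles peaking at 2, 4, 6, 8 with
supports 0–4, 2–6, 4–8, 6–10. Degrees below 1e-12 are treated as zero
so float dust at breakpoint edges cannot fire rules.

The model ships as editable YAML (`src/fuzzyheart/data/heart_model.yaml`)
validated by a pydantic schema; save→load round-trips are identity.

## Knowledge base

A rule assigns one output class to a full conjunction of one term per
input; the complete base has 4·3·2·5·3·4·3 = 4320 rules, indexed by
antecedent tuple. Rule text is parsed from the standard
"IF (Var is Term AND …) THEN Status is Class" dialect (a colon/
semicolon dialect is also accepted), clause order-independently, with
synonym normalization (XHigh → ExtraHigh, Middle → Mid, "Normal"
HbA1c/heart rate → Healthy). An infix→postfix (shunting-yard)
converter handles AND/OR expressions with parentheses; the shipped
generator emits pure-AND rules only.

Only nine expert rules are published. The rest are filled in by a
deterministic **weighted ordinal risk score**: each term carries an
ordinal score in risk order (chest pain 0–3; HbA1c 0–2; HDL Healthy 0,
Low 1; LDL 0–4; heart rate 0, 0.5, 2; age 0–3; blood pressure 0–2),
each variable a weight proportional to |Pearson r| from the
correlation analysis below, and the weighted sum is normalized to
[0, 10] and thresholded at 2.5 / 5 / 7.5 into the four classes. A
score exactly on a threshold goes to the riskier class (conservative
clinical default). The nine curated rules are applied as hard
overrides on top. This generator is an explicit stand-in for the
unpublished expert consultation that produced the original 4320
consequents: it is reproducible, monotone by construction (replacing
any term with a riskier one never lowers the class), consistent with
all nine published rules, and swappable via `RiskWeights`.

The base persists as a TSV flat file (id, seven antecedent terms in
canonical order, consequent, provenance); loading re-indexes and
rejects duplicate antecedents.

## Inference

Mamdani throughout: antecedent aggregation by MIN, same-consequent
combination by MAX, implication by clipping the consequent triangle at
the firing strength. The published worked example exercises only
rules with distinct consequents, so the MAX choice for shared
consequents follows standard Mamdani practice rather than a published
number. Firing enumerates the Cartesian product of the record's
active terms (≤ 2 per graded variable, 1 for chest pain → ≤ 128 index
lookups) instead of scanning all 4320 rules; tests verify equivalence
against a full-scan oracle. Clipped curves are kept as exact
polylines (crossing points inserted analytically), never sampled;
a grid evaluator exists only as a test oracle.

## Defuzzification

* **WA** — Σ sᵢ·peakᵢ / Σ sᵢ over fired consequents, peak being the
  triangle apex (height method).
* **SA** — Σ areaᵢ·centroidᵢ / Σ areaᵢ over the *individually*
  clipped consequent sets, with exact piecewise-linear integration
  (area by trapezoid formula, moment by the closed form for linear
  segments). Overlap between sets counts once per set. The
  alternative union-envelope centroid reading was evaluated and
  rejected: on the worked example it yields 6.6694 against 6.7183 for
  the per-set reading, and only the per-set reading reproduces the
  published end-to-end score of 6.44 (per-set mean 6.4394 vs union
  6.423). The union centroid remains pinned in a test as
  documentation of the gap.
* **MM** — mean of the x-region where the pointwise-MAX aggregate
  attains its maximum. The maximal region is the union of the clip
  plateaus of the top-strength terms (ties within 1e-9); overlapping
  or touching plateaus merge, disjoint ones average by length, and
  degenerate point plateaus (strength exactly 1) average by count.

Final score = (WA + SA + MM)/3, reported to 2 decimals in user output
with full precision retained internally. Classification picks the
output term with maximal membership at the score, ties to the riskier
class; at the two universe endpoints, where all triangle memberships
are zero, the nearest apex decides (score 0 → Healthy, 10 → HighRisk).

## Correlation analysis

For each input, the midpoints of its term supports (for chest pain
these are exactly the codes 1/3/5/7) are paired in risk order with
output-class midpoints spread linearly from 2 to 8 — for k = 4 terms
that is (2, 4, 6, 8), for k = 2 the extremes (2, 8), so the
protective HDL pairs Low↔8, Healthy↔2 and scores r = −1 while chest
pain scores r = +1. For k = 3 and k = 5 the linear spread (2, 5, 8)
and (2, 3.5, 5, 6.5, 8) generalizes the anchored cases; those
magnitudes (≈ 0.99–1.0) only serve as generator weights. The Pearson
coefficient itself is delegated to `scipy.stats.pearsonr` and
cross-checked in tests against a hand-written two-pass oracle;
zero-variance samples are rejected.

## Evaluation and fixtures

Classification accuracy is correct/total·100 over a labeled record
set, with a 4×4 confusion matrix; out-of-range records are excluded
and counted, matching the rejection semantics of the interactive
path. The original system was benchmarked on an external clinical
dataset that cannot be reconstructed from its description (three of
the seven attributes have no column there and the mapping is
unpublished), so the shipped evaluation is grounded in synthetic
fixtures instead:

* **random-uniform** — chest-pain codes drawn from {1,3,5,7}, other
  attributes uniform over their universes, labeled by running the
  shipped pipeline (self-labeled, hence 100 % self-consistency by
  construction — this validates the determinism and totality of the
  pipeline, not its clinical accuracy);
* **grid-corners** — the 2⁷ universe-corner combinations, self-labeled;
* **class-archetypes** — records built from the term peaks of one
  curated rule per class, so the archetype rule fires at strength 1
  and the label is known a priori.

Fixtures are seeded (`numpy.random.default_rng`) and bit-reproducible.
What passing these tests shows: the pipeline is total, deterministic,
monotone, and exactly reproduces every published number. What it does
not show: agreement with real patient outcomes — uniform sampling has
no clinical covariance structure, and self-labeled accuracy is
tautologically 100 %.

## Numerical choices

Degree floor 1e-12 (rule-firing dust), MM plateau tolerance 1e-9,
partition-of-unity tolerance 1e-9 on 10,000-point grids, SA
analytic-vs-numeric agreement 1e-6 against 10⁶-point trapezoid grids.
Problem sizes in the test suite (1,000 records for index-vs-scan
equivalence, 500 activations for the integration oracle, 10⁴ grid
points per variable) are the smallest sizes at which the checked
properties are exercised across every breakpoint and term
combination.

## Known limitations

* The 4311 generated consequents are a principled stand-in, not the
  original expert knowledge; any disagreement with the unpublished
  original base is invisible to desk validation.
* Chest-pain interval width (2) is an assumption; only the four codes
  are meaningful inputs.
* No OR-antecedents in the shipped base (the parser and postfix
  evaluator support them), no product implication, no Sugeno/TSK
  path, no Gaussian or type-2 sets, and no training: the system has
  no fitted parameters.
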