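# fuzzyheart

A Mamdani fuzzy-logic expert system for heart-disease risk scoring.

Clinical decision support for cardiovascular risk lives with vague,
overlapping categories — a blood pressure of 126 mmHg is *mostly*
normal and *a little* high at the same time. `fuzzyheart` models seven
patient attributes — chest-pain type (codes 1/3/5/7), HbA1c (%), HDL
and LDL cholesterol (mg/dL), heart rate (bpm), age (years), and
systolic blood pressure (mmHg) — as linguistic variables with
piecewise-linear membership functions, reasons over a complete
knowledge base of 4320 IF–THEN rules, and returns a crisp 0–10 risk
score classified as Healthy, LowRisk, MediumRisk, or HighRisk. It is
aimed at people studying or building rule-based clinical decision
support: everything is inspectable, deterministic, and auditable down
to the individual fired rule.

## The model

1. **Fuzzification.** Each crisp input x is mapped to degrees
   μ_term(x) ∈ [0, 1] by triangular/trapezoidal/shoulder membership
   functions that form a partition of unity (degrees sum to 1
   everywhere), so at most two terms are active per variable.
   Chest-pain types are non-overlapping crisp sets.
2. **Inference (Mamdani).** Every rule is a conjunction of one term
   per input. Its firing strength is the MIN of the seven antecedent
   degrees, G = min(g_chest pain, g_HbA1c, g_HDL, g_LDL, g_heart rate,
   g_age, g_BP); rules sharing a consequent combine by MAX, and each
   fired consequent triangle is clipped at its strength.
3. **Defuzzification.** Three readings of the clipped output sets are
   averaged: the weighted average of apexes (WA), the area-weighted
   mean of per-set centroids (SA), and the mean of maxima (MM):
   score = (WA + SA + MM) / 3.
4. **Knowledge base.** Only nine expert rules are published; the
   remaining consequents are generated by a deterministic weighted
   ordinal risk score (term scores in risk order, variable weights
   proportional to |Pearson r| between term midpoints and class
   midpoints, thresholds at 2.5/5/7.5) with the published rules as
   hard overrides. See `docs/methods.md` for the full account.

## Worked example

The standard diagnostic test case — atypical chest pain (5), HbA1c
10 %, HDL 30, LDL 141, heart rate 60, age 59, blood pressure 126:

```sh
$ fuzzyheart diagnose --chest-pain 5 --hba1c 10 --hdl 30 --ldl 141 \
    --heart-rate 60 --age 59 --blood-pressure 126 --trace
risk score 6.44 (MediumRisk); WA=6.6000 SA=6.7183 MM=6.0000
  rule 3172 [curated] -> MediumRisk @ 0.7000
  rule 3173 [curated] -> HighRisk @ 0.3000
```

Blood pressure 126 fuzzifies to Normal = (140−126)/20 = 0.7 and
High = 0.3; every other attribute sits fully inside one term. Two
rules fire, MIN gives strengths 0.7 (MediumRisk) and 0.3 (HighRisk),
and the three defuzzifiers yield WA = 6.6, SA = 6.7183, MM = 6.0,
averaging to 6.44 — a medium risk.

Other entry points:

```sh
fuzzyheart rules generate --out rules.tsv   # the complete 4320-rule base
fuzzyheart correlate                        # per-variable Pearson r (+1 chest pain, -1 HDL)
fuzzyheart fixtures --n 100 --seed 7 --out fx.csv
fuzzyheart evaluate --input fx.csv          # classification accuracy + confusion matrix
```

The same operations are available as a library (`fuzzyheart.DiagnosisSystem`,
`generate_rule_base`, `correlation_report`, `evaluate`, ...).

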