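"""Defuzzification: three crisp readings of the clipped output sets,
averaged into the final risk score.

* **WA** (weighted average): firing-strength-weighted mean of the
  consequent triangle apexes (height method).
* **SA** (sum of areas): area-weighted mean of the centroids of the
  individually clipped consequent sets — overlap between sets counts
  once per set, not once in a union envelope.
* **MM** (mean of maxima): midpoint of the x-plateau where the
  pointwise-MAX aggregate attains its maximum; multiple disjoint
  plateaus average by plateau length.

The reported score is the arithmetic mean (WA + SA + MM) / 3,
classified into Healthy / LowRisk / MediumRisk / HighRisk by maximal
output-term membership, ties resolving to the riskier class.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import ActivationSet, clip_outputs
from .errors import DefuzzificationError
from .membership import polyline_area, polyline_centroid
from .variables import LinguisticVariable

#: Memberships within this of the maximum count as maximal (MM plateaus).
PLATEAU_TOL = 1e-9


@dataclass(frozen=True)
class DiagnosisResult:
    """Crisp risk score with its three defuzzifier components and trace."""

    wa: float
    sa: float
    mm: float
    crisp: float
    label: str
    activation: ActivationSet

    def __str__(self) -> str:  # human-readable one-liner for the CLI
        return (f"risk score {self.crisp:.2f} ({self.label}); "
                f"WA={self.wa:.4f} SA={self.sa:.4f} MM={self.mm:.4f}")


def _require_nonempty(act: ActivationSet) -> None:
    if not act.strengths:
        raise DefuzzificationError("no rule fired; defuzzification undefined")


def defuzz_wa(act: ActivationSet, output: LinguisticVariable) -> float:
    """Weighted average of consequent apexes, weighted by firing strength."""
    _require_nonempty(act)
    total = sum(act.strengths.values())
    if total <= 0:
        raise DefuzzificationError("zero total firing strength")
    return sum(
        s * output.term(term).peak(output.universe)
        for term, s in act.strengths.items()
    ) / total


def defuzz_sa(act: ActivationSet, output: LinguisticVariable) -> float:
    """Area-weighted mean of per-set centroids of the clipped consequents.

    Each consequent set is integrated exactly (piecewise-linear
    geometry); overlapping sets each contribute their own full area.
    """
    _require_nonempty(act)
    clipped = clip_outputs(act, output)
    total_area = 0.0
    total_moment = 0.0
    for pts in clipped.values():
        area = polyline_area(pts)
        total_area += area
        total_moment += area * polyline_centroid(pts)
    if total_area <= 0:
        raise DefuzzificationError("zero total clipped area")
    return total_moment / total_area


def defuzz_mm(act: ActivationSet, output: LinguisticVariable) -> float:
    """Mean of maxima of the pointwise-MAX aggregate of clipped sets.

    The aggregate's maximum equals the largest firing strength; its
    maximal region is the union of the top-strength terms' clip
    plateaus.  Overlapping or touching plateaus merge; disjoint ones
    average by length (degenerate single-point plateaus by count).
    """
    _require_nonempty(act)
    top = max(act.strengths.values())
    clipped = clip_outputs(act, output)
    intervals: list[tuple[float, float]] = []
    for term, s in act.strengths.items():
        if s < top - PLATEAU_TOL:
            continue
        xs = [x for x, y in clipped[term] if y >= top - PLATEAU_TOL]
        intervals.append((min(xs), max(xs)))
    intervals.sort()
    merged: list[list[float]] = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1] + PLATEAU_TOL:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    lengths = [hi - lo for lo, hi in merged]
    mids = [0.5 * (lo + hi) for lo, hi in merged]
    if sum(lengths) <= PLATEAU_TOL:
        return sum(mids) / len(mids)
    return sum(length * m for length, m in zip(lengths, mids)) / sum(lengths)


def classify(crisp: float, output: LinguisticVariable) -> str:
    """Label of the output term with maximal membership at ``crisp``.

    Terms are ordered by increasing risk, so scanning with ``>=``
    resolves exact ties to the riskier class.
    """
    output.check_in_range(crisp)
    best_term, best_deg = None, -1.0
    for t in output.terms:
        d = t.degree(crisp)
        if d >= best_deg:
            best_term, best_deg = t.term, d
    if best_deg > 0.0:
        return best_term
    # only at the universe endpoints, where the boundary triangles touch
    # zero: fall back to the nearest term peak
    return min(
        output.terms,
        key=lambda t: abs(t.peak(output.universe) - crisp),
    ).term


def defuzz_combined(act: ActivationSet, output: LinguisticVariable) -> DiagnosisResult:
    """Average the three defuzzifiers and classify the result."""
    wa = defuzz_wa(act, output)
    sa = defuzz_sa(act, output)
    mm = defuzz_mm(act, output)
    crisp = (wa + sa + mm) / 3.0
    return DiagnosisResult(wa=wa, sa=sa, mm=mm, crisp=crisp,
                           label=classify(crisp, output), activation=act)
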