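"""Pearson correlation between input-term midpoints and output classes.

Each input variable's linguistic terms are reduced to the midpoints of
their support ranges (for chest pain these are exactly the crisp codes
1/3/5/7) and paired, in risk order, with the output-class midpoints
spread over 2..8 (the four class triangles peak at 2, 4, 6, 8).  The
Pearson coefficient of that pairing measures how strongly — and in
which direction — the variable's linguistic scale tracks the risk
scale: +1 for chest pain, −1 for the protective HDL.  The magnitudes
serve as the variable weights of the rule generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .variables import INPUT_ORDER, LinguisticVariable, VariableModel

#: Midpoints of the four output-class triangles, in risk order.
OUTPUT_MIDPOINTS = (2.0, 4.0, 6.0, 8.0)


@dataclass(frozen=True)
class MidpointSeries:
    """Paired (term midpoint, output-class midpoint) samples for one variable."""

    variable: str
    xs: tuple[float, ...]
    ys: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.xs) != len(self.ys) or len(self.xs) < 2:
            raise ConfigurationError(
                f"{self.variable}: need >= 2 paired midpoints, "
                f"got {len(self.xs)} x {len(self.ys)}"
            )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


def pearson_r(xs, ys) -> float:
    """Textbook Pearson correlation coefficient of two equal-length samples."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation undefined for zero-variance sample")
    return float(stats.pearsonr(xs, ys).statistic)


def build_midpoint_series(var: LinguisticVariable,
                          output: LinguisticVariable) -> MidpointSeries:
    """Pair a variable's term-support midpoints with output-class midpoints.

    Terms are stored in risk-increasing order, so the k-th term pairs
    with the k-th of k output midpoints spread linearly from the
    lowest-risk class midpoint (2) to the highest (8).  A variable with
    fewer terms than classes anchors onto the extreme classes — HDL's
    protective direction (Healthy↔2, Low↔8) falls out of the ordering.
    """
    if var.role != "input":
        raise ConfigurationError(f"{var.name} is not an input variable")
    xs = tuple(
        0.5 * (s[0] + s[1])
        for s in (t.support(var.universe) for t in var.terms)
    )
    k = len(xs)
    ys = tuple(np.linspace(OUTPUT_MIDPOINTS[0], OUTPUT_MIDPOINTS[-1], k))
    return MidpointSeries(variable=var.name, xs=xs, ys=ys)


def correlation_report(model: VariableModel) -> dict[str, CorrelationResult]:
    """Signed Pearson r of every input variable against the risk classes."""
    report = {}
    for name in INPUT_ORDER:
        series = build_midpoint_series(model.input(name), model.output)
        report[name] = CorrelationResult(
            r=pearson_r(series.xs, series.ys), n=len(series.xs)
        )
    return report
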